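import numpy as np
import pandas as pd
import pytest

from gutlink.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by read-only tests."""
    cfg = GeneratorConfig(seed=11, n_samples=120, n_species=60, n_enzymes=40,
                          n_proteins=20, n_metabolites=30)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_metadata(n_art_suppressed_20=152, n_art_mid=31, n_art_high=16,
                  n_no_art=50):
    """Metadata with an exact ART / viral-load composition."""
    rows = []
    for _ in range(n_art_suppressed_20):
        rows.append({"art": 1, "viral_load": 10.0})
    for _ in range(n_art_mid):
        rows.append({"art": 1, "viral_load": 100.0})
    for _ in range(n_art_high):
        rows.append({"art": 1, "viral_load": 5000.0})
    for _ in range(n_no_art):
        rows.append({"art": 0, "viral_load": np.nan})
    frame = pd.DataFrame(rows)
    frame.index = [f"S{i:04d}" for i in range(len(frame))]
    frame["plaque"] = 0
    frame.loc[frame.index[: len(frame) // 4], "plaque"] = 1
    return frame
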