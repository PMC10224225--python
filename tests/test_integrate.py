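"""Cross-omics screens, species selection, score and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from gutlink import assoc, integrate
from gutlink.containers import AssociationRecord, ValidationError


class TestCorrelationScreen:
    def test_matches_elementwise_partial_spearman(self, rng):
        n = 40
        F = pd.DataFrame(rng.normal(size=(n, 5)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"f{j}" for j in range(5)])
        T = pd.DataFrame(rng.normal(size=(n, 3)), index=F.index,
                         columns=[f"t{j}" for j in range(3)])
        C = pd.DataFrame(rng.normal(size=(n, 2)), index=F.index)
        out = integrate.correlation_screen(F, T, covariates=C)
        assert len(out) == 15
        for _, row in out.iterrows():
            ref = assoc.partial_spearman(F[row.feature_id], T[row.target_id],
                                         C.to_numpy())
            assert row.rho == pytest.approx(ref["rho"], abs=1e-10)
            assert row.p == pytest.approx(ref["p"], rel=1e-8)

    def test_perfect_monotone_pair_tops_screen(self, rng):
        n = 30
        F = pd.DataFrame(rng.normal(size=(n, 4)),
                         index=[f"s{i}" for i in range(n)],
                         columns=list("abcd"))
        T = pd.DataFrame({"t": np.exp(F["a"])}, index=F.index)
        out = integrate.correlation_screen(F, T)
        hit = out[out.feature_id == "a"].iloc[0]
        assert hit.rho == pytest.approx(1.0)
        assert hit.q == out.q.min()

    def test_no_shared_samples_errors(self, rng):
        F = pd.DataFrame(rng.normal(size=(12, 2)), index=[f"x{i}" for i in range(12)])
        T = pd.DataFrame(rng.normal(size=(12, 2)), index=[f"y{i}" for i in range(12)])
        with pytest.raises(ValidationError):
            integrate.correlation_screen(F, T)


class TestConditionalSelection:
    def test_single_candidate_reduces_to_marginal_model(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        X = pd.DataFrame({"only": x})
        sel = integrate.conditional_selection(y, X, alpha=0.05)
        marginal = assoc.fit_linear(y, x)
        joint = sel.joint_model_.iloc[0]
        assert joint["beta"] == pytest.approx(marginal.beta, abs=1e-10)
        assert joint["selected"] == (marginal.p < 0.05)

    def test_collinear_pair_keeps_the_causal_species(self):
        wins = 0
        reps = 30
        for seed in range(reps):
            r = np.random.default_rng(seed)
            n = 1000
            a = r.normal(size=n)
            b = 0.8 * a + math.sqrt(1 - 0.64) * r.normal(size=n)
            y = 0.5 * a + r.normal(size=n)
            sel = integrate.conditional_selection(
                y, pd.DataFrame({"causal": a, "shadow": b}), alpha=0.05)
            wins += (set(sel.species_ids_) == {"causal"})
        assert wins / reps >= 0.8

    def test_orthogonal_candidates_match_marginal_decisions(self, rng):
        n = 200
        Q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        X = pd.DataFrame(Q, columns=list("abcd"))
        y = (0.4 * Q[:, 0] + 0.02 * Q[:, 2] + 0.05 * rng.normal(size=n))
        sel = integrate.conditional_selection(y, X, alpha=0.05)
        marginal = {f: assoc.fit_linear(y, X[f]).p < 0.05 for f in X.columns}
        joint = dict(zip(sel.joint_model_.feature_id, sel.joint_model_.selected))
        assert joint == marginal

    def test_guard_on_sample_size(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 10)))
        with pytest.raises(ValidationError):
            integrate.conditional_selection(rng.normal(size=10), X)

    def test_aliased_candidate_dropped_with_warning(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.warns(UserWarning, match="aliased"):
            sel = integrate.conditional_selection(rng.normal(size=n), X)
        assert len(sel.dropped_) == 1


class TestGMBScore:
    def test_zero_weights_give_zero_score(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        sc = integrate.build_gmb_score(["a", "b"], [0.0, 0.0], X, standardize=False)
        assert np.allclose(sc.scores, 0.0)

    def test_single_species_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        sc = integrate.build_gmb_score(["b"], [1.0], X, standardize=False)
        assert np.allclose(sc.scores, X["b"])

    def test_linearity_in_weights(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        w1 = np.array([0.5, -0.2, 0.0, 0.1])
        w2 = np.array([0.1, 0.3, -0.4, 0.0])
        s1 = integrate.build_gmb_score(list("abcd"), w1, X, standardize=False).scores
        s2 = integrate.build_gmb_score(list("abcd"), w2, X, standardize=False).scores
        s12 = integrate.build_gmb_score(list("abcd"), w1 + w2, X,
                                        standardize=False).scores
        assert np.allclose(s12, s1 + s2, atol=1e-12)

    def test_missing_species_listed(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        with pytest.raises(ValidationError, match="ghost"):
            integrate.build_gmb_score(["a", "ghost"], [1.0, 1.0], X)


def hypergeom_enumeration(N, K, n, k):
    """Exhaustive upper-tail enumeration oracle."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


class TestECEnrichment:
    def records(self, pvals):
        return [AssociationRecord(feature_id=f"e{i}", model_tag="m", beta=0.0,
                                  se=1.0, p=p) for i, p in enumerate(pvals)]

    def test_hand_computed_tail(self):
        # N=20, K=5, n=8, k=5 -> C(5,5) C(15,3) / C(20,8) = 455/125970
        pvals = [0.001] * 8 + [0.5] * 12
        ec = {f"e{i}": ("cat" if i < 5 else "other") for i in range(20)}
        # the 5 category members are all significant (they sit in the first 8)
        out = integrate.ec_enrichment(self.records(pvals), ec)
        row = out[out.category_id == "cat"].iloc[0]
        assert row["hits"] == 5 and row["category_size"] == 5
        assert row["p"] == pytest.approx(455 / 125970, abs=1e-12)
        assert row["p"] == pytest.approx(0.003612, abs=5e-7)

    def test_matches_enumeration_oracle_all_small_universes(self, rng):
        for N in range(5, 26, 5):
            for _ in range(5):
                K = int(rng.integers(1, N))
                n = int(rng.integers(1, N))
                pvals = np.full(N, 0.5)
                sig_idx = rng.choice(N, size=n, replace=False)
                pvals[sig_idx] = 0.001
                cat_idx = rng.choice(N, size=K, replace=False)
                ec = {f"e{i}": ("cat" if i in set(cat_idx) else f"z{i}")
                      for i in range(N)}
                out = integrate.ec_enrichment(self.records(pvals), ec)
                row = out[out.category_id == "cat"].iloc[0]
                k = len(set(sig_idx) & set(cat_idx))
                assert row["p"] == pytest.approx(
                    hypergeom_enumeration(N, K, n, k), abs=1e-12)

    def test_no_significant_enzymes_all_p_one(self):
        out = integrate.ec_enrichment(self.records([0.5] * 6),
                                      {f"e{i}": "c" for i in range(6)})
        assert (out["p"] == 1.0).all()

    def test_empty_category_hits_never_flagged(self):
        pvals = [0.001] * 3 + [0.9] * 7
        ec = {f"e{i}": ("hot" if i < 3 else "cold") for i in range(10)}
        out = integrate.ec_enrichment(self.records(pvals), ec)
        cold = out[out.category_id == "cold"].iloc[0]
        assert cold["hits"] == 0
        assert cold["p"] >= 0.5
        assert not cold["enriched"]

    def test_unmapped_enzyme_errors(self):
        with pytest.raises(ValidationError, match="e1"):
            integrate.ec_enrichment(self.records([0.1, 0.2]), {"e0": "c"})


class TestAttenuation:
    def test_formula(self, rng):
        rep = integrate.AttenuationReport if False else None
        # direct formula check through the public API: build data where the
        # adjusted fit is the base fit (independent adjuster)
        n = 3000
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 0.6 * x))))
        noise = rng.normal(size=n)
        out = integrate.attenuation_analysis(y, x, None, noise)
        assert abs(out.percent_attenuation) < 12.0
        assert not out.collinearity_warning

    def test_quarter_attenuation_value(self):
        # percent attenuation is a pure function of the two betas
        base = AssociationRecord("f", "base", beta=0.4, se=0.1, p=0.01)
        adj = AssociationRecord("f", "adj", beta=0.3, se=0.1, p=0.01)
        pct = 100 * (abs(base.beta) - abs(adj.beta)) / abs(base.beta)
        assert pct == pytest.approx(25.0)

    def test_full_mediation_approaches_total_attenuation(self, rng):
        n = 4000
        x = rng.normal(size=n)
        mediator = x + rng.normal(size=n)  # exposure -> mediator -> outcome
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 1.5 * mediator))))
        out = integrate.attenuation_analysis(y, x, None, mediator)
        assert out.percent_attenuation > 80.0
        assert not out.collinearity_warning

    def test_default_cohort_score_points_toward_plaque(self):
        """On default synthetic cohorts the screen->selection->score chain
        produces a score whose plaque association has the planted positive
        direction (median over seeds; per-seed sign flips are expected at
        the default signal-to-noise ratio)."""
        from gutlink import preprocess
        from gutlink.synthetic import GeneratorConfig, generate_cohort
        betas = []
        for seed in range(30):
            cfg = GeneratorConfig(seed=seed, n_samples=320, n_species=316,
                                  n_enzymes=3, n_proteins=3, n_metabolites=2)
            c = generate_cohort(cfg)
            intclr = preprocess.int_clr_transform(
                preprocess.filter_features(c["species"])).data
            target = preprocess.int_transform(
                np.log(c["metabolites"].data[["met_ImP"]])).data.iloc[:, 0]
            screen = integrate.correlation_screen(intclr, target.to_frame())
            cand = list(screen.loc[screen.significant, "feature_id"])
            if not cand:
                continue
            sel = integrate.conditional_selection(target.to_numpy(),
                                                  intclr[cand], alpha=0.05)
            score = sel.transform(intclr)
            cov = assoc.build_design(c["metadata"][["age", "hiv", "site"]])
            rec = assoc.fit_logistic(c["metadata"]["plaque"].to_numpy(),
                                     score.to_numpy(), cov)
            betas.append(rec.beta)
        assert np.median(betas) > 0
        assert np.mean(np.array(betas) > 0) > 0.75

    def test_independent_adjuster_no_attenuation(self, rng):
        n = 4000
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1 + 0.5 * x))))
        adj = rng.normal(size=(n, 2))
        out = integrate.attenuation_analysis(y, x, None, adj)
        assert abs(out.percent_attenuation) < 10.0
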