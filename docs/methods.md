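# Methods

`gutlink` re-implements, as a tested and reusable pipeline, a
multi-omics integration analysis linking gut metagenomic species and
functions, serum proteomic inflammatory markers, and plasma metabolites
(most prominently a microbially produced imidazole-propionate-like
metabolite) to carotid artery plaque. This note documents the models,
the defaults and why they were chosen, what the synthetic cohort does
and does not emulate, and the numerical choices that matter.

## Transformation chain

Species abundances are compositional. The pipeline works on:

* **CLR** (centered log-ratio): per sample *i*, feature *j*,
  `clr_ij = ln(x̃_ij) − mean_j ln(x̃_ij)` on zero-replaced relative
  abundances. Default zero replacement is half the smallest nonzero
  relative abundance in the table, mirroring the half-minimum
  imputation convention used for below-detection metabolites. CLR rows
  sum to zero and the transform is invariant to per-sample scaling
  (both asserted to 1e-9 in the tests).
* **INT** (rank-based inverse-normal transform), column-wise with the
  Blom offset c = 3/8: the value of rank *r* among *n* maps to
  `Φ⁻¹((r − c)/(n − 2c + 1))`, average ranks for ties. Blom is the
  common epidemiological convention; ties by average rank keep the
  transform deterministic and antisymmetric.
* **INT-CLR**: INT applied feature-wise to CLR abundances — the scale
  on which the gut-microbiota score is built.

INT is a within-cohort rank transform: it has no meaningful
out-of-sample mapping, so the transformer re-ranks whatever matrix it
is applied to.

## Feature filtering and QC

* Species: drop features with prevalence < 20 % (fraction of samples
  with count > 0) or mean relative abundance < 0.001 % (1e-5). Both
  rules are strict inequalities: a feature sitting exactly on a
  threshold is retained. Filtering happens before CLR.
* Proteins (NPX, log2 scale): keep markers detected in strictly more
  than 75 % of samples.
* Metabolites: keep features with CV < 30 % (SD/mean on observed
  values) and missing rate < 20 %; remaining missing values are imputed
  with half the feature's minimum observed value, then log-transformed
  for modelling.

## Differential abundance

Three complementary screens, run on the same filtered species table:

1. **LDA effect size (two-class)** — Kruskal–Wallis prefilter at
   α = 0.05; abundances rescaled so the table maximum maps to 1e6; 30
   bootstrap rounds, each a class-stratified 2/3 subsample, fitting a
   ridge-regularized linear discriminant (λ = 1e-3 · trace(S)/m); the
   per-feature effect is `|(w_f + Δμ_f)/2|` (discriminant coefficient
   plus class-mean difference on the scaled data), and the reported
   score is `log10(1 + mean bootstrap effect)`, signed positive for
   case enrichment. Features pass at |score| > 3 (strict). The
   published tool's internals are under-documented, so this is a fixed,
   documented variant: no subclass/Wilcoxon stage (the two-class design
   has none), and the bootstrap RNG is seeded; results are invariant to
   sample order (samples are sorted internally before subsampling).
   Exact numeric replication of any particular external implementation
   is not claimed.
2. **CLR-logistic screen** — per-species covariate-adjusted logistic
   regression of plaque on standardized CLR abundance (odds ratios per
   SD), BH-FDR at 10 %.
3. **ANCOM-style W** — for every feature pair (i, j), OLS of
   `ln(x_i/x_j)` on outcome plus covariates; within feature *i* the
   m − 1 pairwise outcome p-values are BH-adjusted and W_i counts those
   below α. Detection is declared at W_i/(m−1) ≥ 0.6 (0.7/0.8/0.9 also
   reported). Per-feature BH over pairwise p-values mirrors the
   second-generation ANCOM approach while staying self-contained. W is
   invariant to per-sample scaling by construction (log-ratio identity).

## Regression backbone

Logistic fits use a compact IRLS Newton solver (the calibration studies
run tens of thousands of per-feature fits; the solver is cross-checked
against statsmodels to 1e-6). Wald 95 % CIs, `exp(β ± 1.96·se)`, are
used throughout — symmetric on the log-odds scale and cheap. Exposures
are standardized by the analysis sample's SD *after* transformation, so
effects read "per SD of CLR (or INT-CLR) abundance". Quasi-separation
and non-convergence are flagged on the result record rather than
raised, so screens never crash on a pathological feature. Categorical
covariates are reference-coded with the most frequent level as
reference (deterministic).

Partial Spearman correlation ranks both variables (average ranks),
residualizes each on the covariates, and Pearson-correlates the
residuals; p from a t distribution with n − 2 − k df. It reduces
exactly to ordinary Spearman with no covariates and is invariant to
strictly monotone transforms of either variable.

## PLS-DA of the inflammatory panel

PLS1 NIPALS with the binary plaque status as the single (centered)
response and column-standardized markers — identical to two-column
dummy PLS2 for two classes and deterministic (no random
initialization). Eight components by default; per-component logistic
models (scores standardized per SD) and the top five contributors per
component ranked by |loading| (loadings, not weights, because the
loading is the marker's representation in the component; exact ties
break lexicographically by marker id). Component scores are mutually
orthogonal (asserted to 1e-8).

## Community-level analyses

Alpha diversity: Shannon (natural log), Simpson (1 − Σp²), Chao1
(`S_obs + F1²/(2·F2)`, switching to the bias-corrected
`S_obs + F1(F1−1)/2` when F2 = 0 to avoid division by zero; integer
counts required). Beta diversity: Bray–Curtis and normalized weighted
UniFrac `Σ_b l_b|p_A − p_B| / Σ_b l_b(p_A + p_B)`, computed from a
branch×leaf incidence matrix (vectorised; cross-checked against
scikit-bio). PERMANOVA uses the among/within partition of squared
distances, with an add-one permutation p-value
`(1 + #{F* ≥ F})/(1 + n_perm)` and 999 seeded permutations by default
(the add-one form avoids p = 0; the seed makes runs reproducible —
scikit-bio's implementation takes no seed, which is why this one is
written out, and its pseudo-F is used as a cross-check in the tests).

## Integration arm

* **Correlation screens** across layers are (partial) Spearman with a
  single BH adjustment per screen, significant at q < 0.10. The
  species–metabolite screen is unadjusted Spearman by default (the
  covariate-adjusted mode is exposed); the vectorised screen matches
  elementwise partial-Spearman calls to 1e-10.
* **Conditional selection**: all screen-significant species enter one
  joint least-squares model of the target metabolite with covariates
  ("mutual adjustment"); species with joint-model p < 0.05 are declared
  independently associated, and their joint betas are the score
  weights. p < 0.05 is the conventional reading of "independent
  association" in a mutual-adjustment model. Aliased candidates are
  dropped with a warning and the model refitted; a guard requires
  n > candidates + covariates + 1, and the pipeline caps candidates at
  that guard by ascending q if a screen is unusually generous.
* **Gut-microbiota (GMB) score**: per-sample weighted sum of INT-CLR
  abundances of the selected species, standardized to unit SD by
  default so downstream ORs read "per SD of the score".
* **EC level-III enrichment**: enzymes significant at p < 0.05 in the
  covariate-adjusted linear screen; per category a hypergeometric
  upper-tail p `P(X ≥ k | N, K, n)`, BH across categories, enriched at
  q < 0.10. Hypergeometric over-representation is the standard
  category-enrichment default and exactly testable (the tests enumerate
  every universe N ≤ 25).
* **Attenuation**: `100·(|β_base| − |β_adjusted|)/|β_base|` on the
  log-odds scale after adding PLS components, the target metabolite, or
  both to the base model — symmetric for protective and risk effects.
  This is covariate-adjustment attenuation, not a formal mediation
  decomposition (no natural direct/indirect effects are estimated). An
  adjuster correlated with the exposure at |r| > 0.99 sets a warning
  flag.

## Synthetic cohort generator

The generator is first-class, tested code; it emulates the *structure*
of the cohort design described above, not its biology:

* ~316 species with log-normal latent abundances, per-feature
  structural-zero fractions up to 0.8, multinomial read sampling at a
  shallow-shotgun depth of 100 000 assigned reads per sample (every
  count row sums exactly to the depth);
* a binary plaque outcome from a logistic model over standardized
  latent-CLR abundances plus covariates, with the intercept calibrated
  by bisection to ≈ 26 % prevalence (84/320);
* covariates: age ~ N(50, 10), a 65 %-prevalence HIV indicator, a
  3-level site factor, ART use among the HIV-positive, and a numeric
  viral load — the smallest set exercising the adjustment, stratified
  and cohort-summary code paths;
* six species with planted plaque ORs (1.47, 0.64, 0.75, 0.71, 0.70,
  0.82 per SD of CLR abundance); 17 producer species (8 positive,
  9 negative, overlapping the five protective plaque species) drive the
  target metabolite through their latent CLR abundances, normalized to
  unit signal SD, plus Gaussian noise (default 1 signal SD); a carrier
  set drives one functional-gene column from relative abundances; a
  subset of protein columns loads on the plaque species and the target
  metabolite (the mediator path the attenuation analysis probes);
* metabolite missingness is left-censored (the lowest values of each
  non-target metabolite are set missing), mimicking below-detection
  values, at a default rate of 5 %.

Design choices that required care:

* **Planted features are detectable by construction.** Planted species
  (the plaque set and the producers) draw their structural-zero
  fraction capped at 0.3 and their mean log abundance from the range
  the sequencing depth resolves, and producer weight magnitudes are
  drawn U(0.3, 0.5) before normalization. In the cohort design this
  generator emulates, the focal species pass the 20 %-prevalence /
  abundance filter and every producer is detectable by both the
  marginal screen and the joint model; a generator whose planted
  features can be silently filtered out or sit below the screen's
  detection floor cannot exercise that design.
* **Zero replacement in the latent CLR uses a per-feature detection
  floor** (half the feature's smallest nonzero abundance), not a global
  table minimum: a global floor places absent samples many SDs below
  the data range and lets an arbitrary replacement magnitude dominate
  the planted cross-layer signals.

What the generator does **not** emulate: read-level sequencing, taxa
correlation structure beyond compositional closure, batch/plate
effects, LC–MS peak artefacts, real covariate–microbiome confounding.
Passing recovery tests therefore demonstrates that the pipeline's
statistics recover planted effects under the assumed sampling model —
not that the method is robust to everything real cohorts contain.

## Problem sizes and calibration results

The calibration suites run at the scale where the asymptotics they
check are meaningful while staying desk-sized: null calibration uses
zero-effect cohorts of n = 400 with 300 species (per-replicate KS
uniformity of the per-feature logistic p-values, aggregated across
replicates at the replicate level because features within a cohort are
compositionally dependent; BH at q < 0.10 keeps the observed global-null
FDR ≤ 0.15; the W statistic at detection 0.6 stays silent in ≥ 90 % of
null cohorts of n = 200, m = 30). Recovery uses a planted ln(1.5)/SD
species effect at n = 400 (median recovered OR within [1.2, 1.9], sign
≥ 90 % of seeds) and the full screen → mutual adjustment → score
pipeline at metabolite noise 0.5 signal SD (score–metabolite
correlation > 0.7 and positive score–plaque direction in ≥ 90 % of
seeds). On cohorts at the generator defaults (noise = 1 signal SD,
n = 320) individual seeds can flip the score–plaque sign; the planted
direction holds in the median across seeds, with a median score OR
≈ 1.3 per SD.

## Known limitations

* The LDA effect-size variant is deliberately fixed and documented, not
  a bit-for-bit replica of any external tool.
* The W-statistic screen refits m(m−1)/2 linear models; above a few
  thousand features this becomes the pipeline's bottleneck.
* Attenuation percentages are descriptive; they carry no causal
  mediation interpretation.
* BH-adjusted p-values are monotone and order-preserving but not a
  fixed point of re-adjustment; q-values should be compared to the FDR
  threshold, never re-adjusted.
* The INT transform is cohort-relative; scores built from INT-CLR
  abundances are not transferable across cohorts without re-ranking.
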