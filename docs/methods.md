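# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## Quantification and normalisation

Targeted MRM lipidomics reports one peak area per lipid feature per
sample plus one spiked internal standard (IS) per lipid class.  The
concentration estimate is linear isotope-dilution quantification:

    c = (A_lipid / A_IS) × c_IS

The IS→class mapping is a platform configuration, validated for
completeness when a table is loaded; an IS with a nonpositive or missing
peak area is treated as an assay failure (hard error naming sample and
class), not silently skipped.  Concentrations are then divided by total
cell-pellet protein (µg, macrophages and liver) or plasma volume (µl,
canonically 50 µl).  Missing peak areas stay missing through this stage —
imputation is a separate, declared step.

## Preprocessing chain

The chain is `filter → KNN impute → TAG collapse → class fractions →
logit → z-score`, applied per tissue, and deterministic throughout.
Matrices carry a stage tag and transitions are checked, so a step cannot
be applied out of order.

* **Missingness filter.** A feature is kept only when its within-tissue
  missing fraction is strictly below 0.5 ("below 50 %" read literally;
  the 5-of-10 boundary case is dropped, and unit-tested).  Missingness is
  computed within tissue because plasma and macrophages detect different
  panels.
* **KNN imputation** (k = 10, configurable) works in feature space:
  neighbours of a feature are the features with the smallest Euclidean
  distance between standardized profiles over pairwise-complete samples
  (root mean squared difference over co-observed samples, so pairs with
  different missingness are comparable).  A missing cell is filled with
  the mean of the k nearest donors' *standardized* values in that
  sample, mapped back to the target feature's observed-cell mean and SD.
  Averaging on the standardized scale is deliberate: neighbour distance
  ignores magnitude, so donors may sit orders of magnitude away in raw
  abundance, and raw-value averaging would inject off-scale values into
  low-abundance (detection-limit-censored) classes and corrupt their
  compositions.  A feature with no co-observed partner falls back to its
  own median, with a warning.
* **TAG isotopomer collapse.** Vendor panels report triacylglycerols once
  per constituent fatty-acyl transition; all features sharing one total
  (carbons, double bonds) are summed per sample into one `TAGcc:db`
  species.  The sum conserves per-sample class totals exactly.  The
  collapse key is the total composition — the natural reading of
  "isotopomers" and the only partition consistent with a 445→95
  reduction.  A composition represented both with and without acyl tags
  is ambiguous and rejected.
* **Class fractions.** Each value is divided by its class total within
  the sample.  This makes the data compositional, with a consequence
  worth stating plainly: a proportional shift of an entire class (every
  member up or down by the same factor) is invisible from this stage on.
  Group effects detectable downstream are within-class compositional
  changes (e.g. the saturated share of FFA rising at the expense of the
  unsaturated share).
* **Logit.** ln(p/(1−p)) after clamping p into [ε, 1−ε] with ε = half the
  smallest nonzero fraction in the matrix, floored at 1e-6 —
  data-adaptive, keeps singleton-class fractions (exactly 1) finite, and
  preserves order.
* **Z-score.** Per feature across samples, with the n−1 SD (so a
  two-sample feature maps to ±1/√2).  Features constant after clamping
  (e.g. singleton classes) carry no information and are dropped with a
  warning.

## Differential abundance

Feature-level comparisons are two-sample t-tests on z-scores;
significance is *counted* at raw P < 0.01 (the stricter BH-adjusted
values are always reported alongside).  Cross-tissue accounting reports
percent significant to one decimal and shared-feature counts on the
name intersection.

Class/stratum-level effects pool each stratum's feature z-scores (one
observation per feature × sample) and model them with disease status as
a categorical fixed effect plus a random intercept per lipid species.
One subtlety: after per-feature z-scoring every feature's mean is
exactly zero, so the species-intercept variance is zero and the REML fit
is degenerate; when statsmodels reports a singular random-effects
covariance the model falls back to its exact fixed-effects limit (the
pooled t-test on the stacked observations), recorded as `model="fixed"`
in the output.  Single-feature strata use the plain t-test directly and
reproduce the feature-level result exactly.  BH adjustment runs across
all strata tested.  The pooled fallback treats feature × sample
observations as independent, which is anti-conservative when features
within a stratum are strongly co-regulated; the null-calibration tests
cover the independent-feature case, and stratum results on heavily
blocked data should be read as descriptive.

Published group characteristics given as n, mean ± SD are compared with
the pooled-variance two-sample t-test (df = n₁+n₂−2); a Welch variant is
available.  Pooled reproduces the published p-values for baseline body
weight, creatinine, phosphorus and PTH to the printed precision; the
published 16-week body-weight, cholesterol and triglyceride rows
reproduce under neither variance rule and are not asserted.

## Correlation networks

**Marginal.** All feature (or class-stratum mean) pairs get a Pearson r;
p-values come from the Fisher Z-transformation (z = atanh r,
SE = 1/√(n−3), two-tailed normal; undefined for n ≤ 3, enforced), with
|r| clamped to 1−1e-12 and p floored at the smallest positive float so
BH input stays in (0, 1].  An edge is *reported* only when BH-adjusted
p < 0.05 AND |r| > 0.7 — the rule is conjunctive.

**DSPC.**  Debiased sparse partial correlations for the p ≳ n regime.
Per node j, a lasso of x_j on the remaining nodes (penalty chosen by
per-node 10-fold cross-validation over a 50-point path) gives the sparse
node-wise precision estimate Θ̂ with τ̂²_j = RSS_j/n + λ_j‖β̂_j‖₁.  The
de-biased estimator

    T = Θ̂ + Θ̂ᵀ − Θ̂ᵀ Σ̂ Θ̂

is asymptotically normal entrywise with variance
(T_jj T_kk + T_jk²)/n, giving per-edge p-values; partial correlations
are −T_jk/√(T_jj T_kk), symmetrised by averaging.  Edges with p < 0.1
are flagged significant (the raw edge p-value defines the network; BH
values are carried as annotation).  For n ≫ p the estimator converges to
the sample inverse-covariance partial correlations (tested at n = 2000,
p = 8, max deviation < 0.05).

**Group comparison.**  For a node stratum (saturated or unsaturated
FFA), the edge universe is every candidate pair incident to the stratum
and present in both groups' networks — identical denominators by
construction.  The 2×2 table of significant vs non-significant edges per
group is tested with the two-sided Fisher exact test (conditional-MLE
odds ratio reported).  Two-sided is the conservative choice when no
direction is pre-specified.

## Fatty-acid metabolism metrics

* **Acylcarnitine ratio** = Σ(C16–C20) / Σ(C5–C14) on raw within-sample
  abundances (a ratio of z-scores would not be scale-meaningful).
  Species outside both windows — including C15 — are excluded;
  unsaturated species count toward their carbon window regardless of
  double bonds, since the windows are defined by chain length only.
  A zero intermediate sum makes the ratio undefined (error).
* **Palmitate enrichment** = E₁ + 2E₂ + 3E₃ + 4E₄ over the fractional
  M+0…M+4 distribution (fractions must sum to 1 ± 1e-6); per-sample
  values are means over technical triplicates (a single replicate is
  accepted with a warning).  No natural-abundance isotope correction is
  applied — none is part of the protocol modelled here — and the tidy
  output carries an `isotope_correction: none` flag as a reminder.
* **ΔΔCt** fold changes use ΔCt = Ct_target − Ct_housekeeping,
  ΔΔCt = ΔCt − mean(ΔCt | reference group), fold = 2^−ΔΔCt.  The
  reference group's geometric-mean fold is 1 by construction.

## Synthetic-data generator

The generator is the package's test bed: it draws a complete study with
the statistical structure the analysis assumes, under conditions chosen
to mirror the modelled design.

* **Design**: two groups × 12 animals (default), tissues PMΦ and plasma;
  the panel map defaults to the platform class sizes (CE 19, MAG 1,
  DAG 39, TAG 445 isotopomers over 95 compositions, FFA 16, PC 65,
  PE 47, PE-O 19, PE-P 41, PI 22, PG 24, LPC 11, PS 26, LPS 1, LPE 10,
  SM 27, HCER 9, LCER 6, DCER 6, CER 10, AC 29; 873 features).
* **Abundances** are log-normal with class geometric means spanning
  three orders of magnitude (the dynamic range typical of targeted
  lipidomics) and per-feature log-SD 0.5.
* **Group effects** are stratum shifts in standardized units applied on
  the log scale; defaults mirror the modelled biology in direction
  (saturated FFA, PG, PE, saturated ether-PE up in CKD macrophages;
  unsaturated FFA, TAG, DAG, PC, SM down; PG/PE/PC up in plasma) with
  magnitude 0.8 SD, the effect size the recovery analyses are specified
  at.  Because of compositionality (above), whole-class default shifts
  document direction but only within-class contrasts are recoverable
  post-normalisation; the recovery simulations therefore program the
  opposite-sign saturation contrast within FFA.
* **Correlation blocks** put a per-sample latent factor behind chosen
  strata with signed loadings, optionally in one group only; residual
  variance is scaled so total feature variance stays constant
  (over-allocated loadings are an error).  Blocks load
  saturation-resolved strata rather than whole classes, again because a
  factor common to an entire class cancels in the fractions.  The
  default block couples unsaturated FFA with unsaturated TAG and DAG
  (loading 0.9) in CKD macrophages only, creating the group-specific
  network structure the contingency comparison is designed to detect.
* **Missingness** defaults to 10 % with a limit-of-detection mechanism:
  cells are censored where log-abundance plus logistic noise falls below
  the matching overall quantile, so low-abundance lipids are missing
  preferentially.  MCAR is available.
* **Peak areas** are back-computed through the IS relation
  (A = c_pre-norm / c_IS × A_IS with log-normal IS areas), so
  quantification inverts generation exactly; with `noise_sd = 0` and no
  missingness the round trip is machine-precision exact (tested).
* **Acylcarnitine profiles** use the separate 29-species AC panel;
  CKD samples scale the C16–C20 window by 0.75, a reduction of the
  β-oxidation ratio of the modest size the modelled study reports as
  borderline.
* **Isotopomer tables** draw triplicate M0–M4 fractions from a Dirichlet
  centred on a shape whose weighted enrichment equals the programmed
  target (default 0.25 in all tissues, equal between groups — the
  modelled finding is *no* group difference in de novo lipogenesis);
  concentration 2000 gives replicate-level noise of a few percent.
* **Ct tables** encode programmed fold changes (Acsl1 5-fold up in CKD;
  Il1b 3-fold, Il6 and Tnfa 2-fold; other Acsls unchanged) with Ct noise
  SD 0.1; with zero noise ΔΔCt recovers the folds exactly (tested).

What the generator does **not** emulate: chromatographic drift and batch
effects, isotope-pattern overlap, non-lognormal heavy tails, biological
covariates (body weight, diet duration), and realistic genome-scale
correlation beyond the programmed blocks.  Passing recovery tests
therefore show the pipeline is correct and calibrated under its own
assumptions, not that those assumptions hold in any particular real
dataset.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` uses: a 500-feature, 12+12 zero-effect study for
null calibration; 100 simulated studies (16 FFA + 16 PC + 20 TAG
features, 12+12) for stratum-shift sign recovery; 20 replicates of a
12-node chain Gaussian graphical model at n = 500 (off-diagonal
precision 0.35) for DSPC edge recovery; and one full default-design
study (873-feature panel, 12+12) for the TAG-collapse count, the
acylcarnitine ratio contrast, liver enrichment and the Acsl1 fold
change.  These sizes keep the whole script under a minute on one CPU
while leaving the Monte-Carlo error small relative to every margin
tested.

## Known limitations

* The mixed model is nominal only: on z-scored features it always
  reduces to its fixed-effects limit (see above).
* DSPC p-values are asymptotic; at n near the minimum (6–12 samples)
  the null edge rate is only approximately the nominal α.
* The Pearson reporting rule (|r| > 0.7 and q < 0.05) is a reporting
  convention, not an error-rate guarantee, and the two thresholds are
  redundant at large n.
* The acylcarnitine ratio ignores species outside both windows by
  definition; panels missing the C5–C14 window entirely cannot be
  scored.
* No covariate adjustment, batch correction or pooled-QC drift
  correction is implemented.
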