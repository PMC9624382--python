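# Methods

## Model and assumptions

The package implements a rank-pair prognostic model. The feature for a
gene pair (a, b) in sample s is the indicator that a's expression
strictly exceeds b's within that sample; ties give 0. The risk score is
linear in these indicators, `score(s) = Σ β_i I_i(s)`, and survival is
modelled with Cox proportional hazards on that score or its
dichotomization. The construction assumes (i) the prognostic signal is
captured by within-sample orderings, so any monotone per-sample
distortion of the platform is irrelevant; (ii) proportional hazards for
the Cox steps; (iii) right-censoring independent of the event process.

Pairs are enumerated unordered with lexicographic orientation
(gene_a < gene_b); a reversed pair carries the same information with the
opposite coefficient sign, so enumerating both would only double the
feature space. Signature files are the exception: their printed order and
orientation are preserved verbatim.

## Filters

* **Gene variability**: genes are kept when the raw (unscaled) median
  absolute deviation of their values across samples is strictly greater
  than 0.5. No consistency constant is applied and values are used on the
  scale provided, because the filter is a relative variability screen,
  not a normality-based estimator.
* **Pair variation**: a binary pair feature is informative only if both
  indicator values occur with non-trivial frequency; pairs whose
  minority-indicator frequency is below 0.2 are dropped. The boundary
  (exactly 0.2) is retained.

## Cox fitting, Kaplan–Meier, tests

Survival estimation is delegated to lifelines: Kaplan–Meier via the
product-limit estimator (censored times tied with event times remain at
risk through the event), the two-group log-rank test, and Cox partial
likelihood with the Efron tie approximation, Newton optimization, Wald
tests and normal-approximation 95% CIs. On tie-free data Efron and
Breslow coincide and the log-rank statistic equals the Cox score test of
the group indicator; the test suite checks both against hand-written
oracles (naive product-limit and O−E loops, brute-force grid
maximization of the Efron partial likelihood). The chi-squared
association test is Pearson's without continuity correction, matching
the closed 2×2 form n(ad−bc)²/(r₁r₂c₁c₂); a corrected variant would be a
one-line change where conservative small-sample behaviour is preferred.

## Signature selection

"Repeated Lasso" is implemented as stability selection:

1. build a 30-point L1 penalty grid from the full-data coordinate-descent
   path (scikit-survival's Coxnet);
2. in each of `n_repeats` rounds, subsample 80% of patients without
   replacement, choose the penalty on that subsample by 3-fold
   cross-validated concordance (preferring the strongest penalty among
   near-ties, i.e. the sparsest model), and record which pairs have
   non-zero coefficients at that penalty;
3. keep pairs selected in at least `selection_threshold` (default 0.5) of
   rounds;
4. refit a single penalized Cox model on the full cohort restricted to
   the kept pairs at the median of the per-round penalties; its non-zero
   coefficients form the signature.

All resampling is driven by one integer seed, so a fitted signature is
byte-reproducible. The default repeat count is 1,000; the test suite and
examples use 50 repeats, which is sufficient for the planted/noise
separation the tests assert at their cohort sizes.

## Risk cutoff

The cutoff between low and high risk is chosen on a fixed-horizon ROC:
patients with an event before 60 months are positives, patients followed
event-free beyond 60 months are negatives, and patients censored earlier
are excluded (their 60-month status is unknown; a time-dependent ROC
would re-weight rather than exclude them and can be swapped in behind
the same operation). The cutoff maximizes Youden's J over midpoints
between consecutive distinct scores, tie-breaking toward the smaller
cutoff; scores exactly at the cutoff are labelled low risk. Validation
cohorts are stratified at the training cutoff unchanged.

## IHC quantification

H-score = 1·pct₁ + 2·pct₂ + 3·pct₃ over the percentages of tumor cells
at weak/moderate/strong staining (0–300). Classes: 0–49 negative, 50–99
1+, 100–199 2+, 200–300 3+, with boundaries belonging to the upper
class; any stained class counts as marker-positive. TIL percentages are
dichotomized at the cohort median (or a supplied constant) with
threshold-equal values sent to "low". The 4-year DFS is read as the
Kaplan–Meier estimate at 48 months (last step at or before the
landmark).

## Synthetic data

The generators produce the minimal structure each pipeline stage needs:

* **Expression**: independent log-normal genes with per-gene location
  drawn from U(1, 4) and scale from U(0.5, 1.5) in natural-log units —
  heavy-tailed positive values with gene-wise dispersion. Planted pair
  genes get equalized locations and scales so the pair indicator splits
  the cohort near 50/50, surviving the variation filter by construction.
* **Survival**: exponential event times with per-sample rate
  λ₀·exp(Σ β_i I_i), λ₀ = 0.01/month by default (median ≈ 69 months,
  a breast-cancer-like follow-up scale); censoring is independent
  U(0, b) with b solved by bisection so the expected censored fraction
  equals the configured rate (default 0.3).
* **IHC cohort**: 282 patients by default with H-class mixture
  (0.564, 0.223, 0.191, 0.021) — the published class frequencies; the
  H-score is a monotone map of one coordinate of a latent bivariate
  normal and the TIL percentages are log-normal transforms of the other,
  giving a one-parameter Gaussian-copula control of their negative
  correlation (default −0.5). Stain percentages are drawn uniformly from
  the set consistent with each H-score. DFS is exponential with hazard
  ratio 1.6 for marker-positive patients — the value implied by 4-year
  DFS of 67.8% vs 78.5% under proportional hazards — with baseline
  hazard −ln(0.785)/48 per month and uniform administrative censoring
  over 104 months of follow-up. TIL medians default to 5% / 10% / 1%
  (total / CD8+ / CD19+).

What these generators deliberately omit: gene–gene correlation networks,
batch and platform effects, non-proportional hazards, and informative
censoring. Tests passing on this synthetic structure therefore establish
correctness of the computations and calibration of the tests under the
assumed model, not robustness of the signature to real-data violations
of it.

## Numerical choices and degenerate inputs

* Indicator ties → 0 (strict inequality).
* MAD threshold comparison is strict (> 0.5).
* Duplicate gene rows on load: keep the highest-median row (configurable
  to first/mean); duplicate sample columns are a hard error.
* Cox convergence: lifelines defaults with convergence warnings surfaced
  as a `converged=False` flag rather than silenced; constant covariates
  and exactly collinear designs raise with the offending names.
* Stability rounds where the penalized fit shrinks every coefficient to
  zero count as "nothing selected", not as failures; if the consensus
  penalty zeroes the restricted refit, the nearest penalty on a fresh
  path is used.
* All-censored Kaplan–Meier input yields the constant-1 curve with a
  warning; a log-rank test with zero events in both groups is an error.
* Percentages in a stain record must lie in [0, 100] and sum to ≤ 100;
  H-scores outside [0, 300] are rejected.
* The published class mixture is renormalized when the printed
  proportions round to a sum slightly off 1 (0.999).

## Problem sizes

Simulation-based tests use cohorts of 120–1,000 samples, 20–60 genes,
up to 53 candidate pairs in selection runs, 50 stability rounds, and
100-replicate null calibrations — sizes at which the planted effects the
tests assert (|β| ≥ 0.8, hazard ratios ≥ 1.6) are comfortably detectable
while the full suite stays fast.

## Known limitations

* The ROC cutoff is a fixed-horizon dichotomization, not time-dependent
  ROC; with heavy early censoring the excluded-censored rule loses data.
* No proportional-hazards diagnostics, stratified Cox, or time-varying
  covariates.
* Stability selection frequencies depend on the subsample fraction and
  CV fold count; the defaults (0.8, 3) are sensible, not optimized.
* Gene identifiers are matched by exact string after trimming and
  uppercasing; no alias or probe-to-symbol mapping is attempted.
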