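# irgpair

Immune-related gene-pair (IRGP) prognostic signatures for survival
analysis of cancer expression cohorts, with the published 26-pair
breast-cancer signature included, plus the immunohistochemistry (IHC)
cohort analysis used to validate a signature gene at the protein level.

## The method

For genes *a*, *b* and patient *s*, the gene-pair feature is the
within-sample ordering indicator

```
I_ab(s) = 1  if  x_a(s) > x_b(s),  else 0
```

Because only the ranking of two genes inside one sample matters, these
features are invariant to any strictly increasing per-sample transform of
the expression values — a signature trained on RNA-seq can be applied to
microarray data with no cross-platform normalization.

The pipeline mirrors the standard IRGP workflow:

1. restrict to an immune gene list, drop low-variability genes
   (median absolute deviation ≤ 0.5);
2. encode all candidate pair indicators and drop near-constant pairs
   (minority-indicator frequency < 20%);
3. screen pairs one at a time with univariate Cox regression (p < 0.05);
4. select a sparse signature by stability-selection Lasso-Cox: repeated
   L1-penalized Cox fits on subsamples, each choosing its penalty by
   cross-validation, keeping pairs selected in a majority of rounds;
5. score patients with the linear risk score
   `score(s) = Σ_i β_i · I_i(s)`, learn the Youden-optimal cutoff from a
   fixed-horizon ROC curve (60 months), and stratify into high/low risk
   (Kaplan–Meier curves, log-rank test, Cox hazard ratios); validation
   cohorts reuse the training cutoff unchanged.

The packaged signature (`irgpair.load_table1_signature()`) is the
published 26-pair breast-cancer model; scoring is exact to its printed
coefficients. The IHC module covers H-score quantification
(`H = 1·pct₁ + 2·pct₂ + 3·pct₃`, range 0–300), classification
(0–49 negative, 50–99 1+, 100–199 2+, 200–300 3+), tumor-infiltrating
lymphocyte (TIL) dichotomization at cohort medians, chi-squared
marker–TIL association, and disease-free-survival comparison.

A synthetic-data module generates log-normal expression, proportional-
hazards survival with planted pair effects and calibrated censoring, and
an IHC cohort whose H-scores and TIL percentages share a negative
Gaussian-copula correlation — so the whole pipeline is testable without
any external download.

## Worked example

```python
import irgpair as ig

cfg = ig.SimulationConfig(
    n_genes=30, n_samples=300, seed=7,
    planted_pairs=[(ig.GenePair("G0001", "G0002"), 1.0)],
    censoring_rate=0.3,
)
expr = ig.simulate_expression(cfg)          # 30 genes x 300 samples
surv = ig.simulate_survival_from_pairs(expr, cfg)

enc = ig.PairEncoder(min_frac=0.2).fit(expr.T)
X = enc.transform(expr.T)                   # samples x pair indicators
sel = ig.LassoCoxSignatureSelector(n_repeats=50, seed=7).fit(X, surv)

model = ig.RiskStratifier(signature=sel.signature_, horizon=60).fit(expr.T, surv)
strat, curves, (stat, p), fit = model.stratify(expr.T, surv)
```

prints, with the quantities it computes:

```
264 informative pairs of 435 candidates
signature: 10 pairs; planted-pair selection frequency 1.00
cutoff 0.835: 140 high / 160 low risk
log-rank chi2 = 82.7 (p = 9.77e-20); HR = 3.62 [2.70, 4.85]
```

The planted pair (a true log hazard ratio of 1.0 on its indicator) is
selected in every stability round; the learned cutoff splits the cohort
into a high-risk group with 3.6-fold higher hazard, and the log-rank test
confirms the separation. Scoring with the published signature instead:

```python
sig = ig.load_table1_signature()            # 26 pairs, exact coefficients
scores = ig.score_expression(sig, my_expression)   # genes x samples frame
```

On the IHC side, `ig.h_score(ig.StainRecord(20, 30, 10))` returns
`110.0` (20% weak + 30% moderate + 10% strong staining), and a simulated
282-patient cohort reproduces the study-like structure: marker-positive
patients have lower 4-year DFS (0.67 vs 0.77, log-rank p = 0.018 at seed
7) and are over-represented in the TIL-low group (chi-squared 32.1).

A small CLI mirrors the library: `irgpair simulate`, `irgpair score`,
`irgpair stratify` (see `irgpair --help`).

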