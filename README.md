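# pathsurv

Pathway-level survival prognosis from gene expression.

Breast-cancer relapse prediction from transcriptomes is hampered by the
dimensionality of gene-level data and the instability of gene signatures.
pathsurv addresses this by modelling at the level of functional units: it
transforms a log2 expression matrix (genes × samples) into **Pathway
Deregulation Scores** (PDS) — one score in [0, 1] per pathway per sample,
measuring how far a sample lies along a principal curve fitted through the
cohort in the pathway's expression subspace — and then builds a sparse
prognostic model on those scores. It is intended for computational
biologists building and validating expression-based prognosis models, with
or without accompanying clinical covariates.

## The model

Given PDS features x (optionally stacked with encoded clinical covariates),
relapse-free survival follows a Cox proportional-hazards model

    h(t | x) = h0(t) · exp(Σᵢ wᵢ xᵢ)

fitted by maximizing the partial likelihood with an L1 (LASSO) penalty
λ·Σ|wᵢ|, which sets most weights exactly to zero and thereby selects the
prognostic pathways. λ is chosen by repeated event-stratified K-fold
cross-validated partial likelihood. Each patient's **prognostic index**
PI = Σᵢ wᵢ xᵢ (the log relative hazard) is thresholded at the k-th largest
training value, k = round(n · training relapse fraction), so the high-risk
group size matches the observed relapse ratio (a quarter-relapse cohort is
cut at the 3rd quartile of PI); the same threshold is applied unchanged to
new cohorts. Risk groups are compared by Kaplan–Meier curves with the
Gehan–Wilcoxon weighted log-rank test, and classification of the binary
relapse flag by ROC/AUC with PI as the score.

Principal curves, the Cox partial likelihood, the Newton and
coordinate-descent (soft-thresholding) fitters and the cross-validated λ
selection are implemented in the package; Kaplan–Meier estimates and
log-rank tests are backed by lifelines, ROC sweeps by scikit-learn.

## Worked example

Simulate a 120-patient cohort in which 2 of 10 pathways drive relapse, score
all pathways, fit the prognosis model, and evaluate it:

```python
from pathsurv import SimulationConfig, simulate_cohort, compute_pds_matrix, PrognosisModel

cfg = SimulationConfig(n_samples=120, n_pathways=10, genes_per_pathway=10,
                       n_causal_pathways=2, seed=7)
expr, gene_sets, clinical, survival, truth = simulate_cohort(cfg)

pds = compute_pds_matrix(expr, gene_sets)          # pathways x samples, in [0, 1]
res = PrognosisModel.from_pds(pds, survival).fit(n_repeats=10, seed=7)
print(res.summary())
report = res.evaluate(pds.data, survival)
print(f"train AUC = {report.auc:.3f}   Wilcoxon log-rank p = {report.p_value:.3g}")
print("true causal pathways:", truth.causal_pathways)
```

Output:

```
Penalized Cox prognosis model
  samples: 120   events: 87
  lambda: 4.79196   selected features: 7/10
  PI threshold: -0.951321 (high-risk fraction 0.725)

feature   block  coefficient  hazard_ratio  univariate_p
 PW_010 genomic     0.883305       2.41888   6.76313e-09
 PW_001 genomic    0.0981711       1.10315     0.0242979
 PW_002 genomic    0.0861395       1.08996      0.292538
 PW_005 genomic    0.0102707       1.01032      0.752274
 PW_004 genomic   0.00676195       1.00678       0.49613
 PW_003 genomic    -0.169524      0.844067      0.810805
 PW_006 genomic    -0.930411      0.394392   9.92583e-11

train AUC = 0.871   Wilcoxon log-rank p = 2.26e-06
true causal pathways: ['PW_006', 'PW_010']
```

The two truly causal pathways (PW_006, PW_010) carry by far the largest
coefficient magnitudes and the smallest univariate Wald p-values; the
cohort's 72.5% relapse fraction fixes the high-risk group size; the
hazard-ratio column is exp(coefficient) on the standardized feature scale.
(Without normal samples the PDS direction per pathway is an arbitrary but
reproducible convention, so a protective-looking sign like PW_006's simply
reflects that pathway's score orientation.)

The same workflow is scriptable from a shell — `pathsurv simulate`, `pds`,
`train`, `predict`, `evaluate`, `combined`, `sensitivity`, `loocv`,
`rank-genes`, or end-to-end via `pathsurv run`; see `pathsurv --help`.

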