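# Methods

pathsurv implements a pathway-level prognosis pipeline for relapse-free
survival from gene expression: expression → Pathway Deregulation Scores (PDS)
via principal curves → L1-penalized Cox proportional-hazards selection →
prognostic-index dichotomization → Kaplan–Meier / weighted log-rank / ROC
evaluation, with a combined clinical+genomic variant and validation
machinery (pathway-subsampling sensitivity, threshold-only LOOCV,
hazard-weighted gene ranking). This note records the models, the defaults
and why, the numerical choices, and what the synthetic cohorts do and do not
establish.

## Pathway deregulation scores

For each pathway the member genes' log2 expression is subset from the
matrix, genes with sample standard deviation below `min_gene_std` (default
0.1, log2 scale) are dropped as uninformative, each remaining gene is
standardized to mean 0 / sd 1, and the samples are projected onto the
leading principal components — the fewest reaching `pca_var_target = 0.85`
cumulative explained variance, capped at min(10, #genes, #samples − 1). A
principal curve (Hastie–Stuetzle) is fitted through the samples in that
space, every sample is orthogonally projected onto the curve, and its
arc-length position λ, measured from an origin end and min–max scaled, is
its PDS ∈ [0, 1]. A pathway with fewer than `min_genes = 3` usable genes is
skipped (recorded, not an error). With a single retained component the curve
degenerates to the real line and the PDS is exactly the min–max scaled
coordinate.

The principal-curve fit alternates (a) projection of the points onto the
current polyline, (b) per-dimension local-average smoothing against λ with a
fractional-span running-mean window (`span = 0.3` of the cohort), and
(c) arc-length reparameterization, starting from the first
principal-component segment. It stops when the relative change of the total
squared orthogonal distance falls below `tol = 1e-3` or after `max_iter =
50` iterations; an iteration that would increase the total squared distance
is rejected and the fit stops there, so the recorded distance trace is
non-increasing by construction. PCA component signs are fixed by forcing
each component's largest-magnitude loading positive, removing SVD sign
ambiguity; the whole scoring pipeline is deterministic.

**Anchoring the origin.** The PDS origin is the curve end representing the
"normal condition". When normal-sample ids are supplied, the origin is the
end nearer their median λ. Tumor-only cohorts have no biological origin, and
any within-cohort heuristic (e.g. anchoring at the most typical sample) can
point the curve in opposite directions in two cohorts, silently negating a
trained model's weights at transfer time — the most typical sample tends to
sit mid-curve, where "nearer end" is a coin flip. The default rule
(`anchor_rule = "reference_gene"`) therefore makes the direction merely
*reproducible* rather than biologically anchored: λ is oriented to increase
with the standardized expression of a deterministic reference gene — the
alphabetically first member gene whose |Pearson correlation with λ| is at
least 0.3, falling back to the best-correlated gene. Because the reference
is named, any cohort sharing the pathway's genes orients the same way and
Cox weights keep their meaning across datasets. The direction is arbitrary
(high PDS need not mean "more deregulated" without normals); the penalized
Cox fit learns the sign. `typical_sample` is available for users who prefer
the distance-from-normal-looking-patient reading within a single cohort.

## Penalized Cox model

The hazard is h(t | x) = h0(t)·exp(xᵀβ); the baseline h0 cancels from the
partial likelihood and is never estimated. Ties use the Breslow
approximation (Efron available for likelihood evaluation and the unpenalized
Newton fit). The LASSO fit maximizes log PL(β) − λ·Σ|βⱼ| by iteratively
reweighted least squares on the quadratic expansion of the partial
likelihood, with cyclic coordinate descent and soft-thresholding in the
inner loop (JIT-compiled; convergence when the largest coefficient update
falls below 1e-6, at most 1000 sweeps per IRLS step, at most 50 IRLS steps).
An IRLS step that would lower the penalized objective is backtracked by
repeated halving toward the previous iterate, so the objective trace is
monotone. At λ ≥ λ_max = max |score at β = 0| the solution is exactly zero
(KKT); the path is fitted over 50 log-spaced values from λ_max down to
10⁻³·λ_max with warm starts.

λ is chosen by repeated K-fold cross-validated partial likelihood
(Verweij–van Houwelingen): a fold's held-out contribution is
loglik(all, β_train) − loglik(train, β_train); folds are event-stratified
and redrawn if a training part has no events; the chosen λ maximizes the
mean across repeats. The library default is 250 repeats of 5 folds, the
figure we consider appropriate for a real cohort; the test-suite and
acceptance runs use 2–10 repeats, which we found selects the same
neighbourhood of the path on the simulated designs at a fraction of the
cost. Features are standardized (mean 0, sd 1, training parameters stored
and re-applied at prediction time) and coefficients are reported on the
standardized scale.

Univariate fits use full Newton–Raphson with step-halving and analytic
gradient/Hessian; hazard ratios are exp(coefficient) and p-values are Wald.

## Prognostic index and risk groups

PI_J = Σᵢ wᵢ x_iJ — the linear predictor (log relative hazard) of the fitted
model, no intercept. The training threshold is the k-th largest training PI
with k = round(n · relapse fraction), so the high-risk group size matches
the training cohort's relapse/non-relapse ratio (a 23–25% relapse cohort is
cut near the 3rd quartile of PI, a 3-to-1 split). Ties at the threshold go
to the high-risk group. The threshold is part of the portable risk model and
is *not* recomputed on test cohorts; per-cohort re-thresholding at a given
fraction is an explicit opt-in (`rethreshold_fraction` /
`--rethreshold-fraction`) for the within-dataset comparison setting.

## Evaluation

Kaplan–Meier product-limit curves (lifelines) summarize each risk group;
the two-group test defaults to the Gehan–Breslow–Wilcoxon weighted log-rank
(weight = number at risk, emphasizing early differences), with the
unweighted log-rank also computed and reported. ROC/AUC uses PI as the score
against the binary relapse flag (censored patients contribute their recorded
flag; relapse is the positive class); AUC is the exact Mann–Whitney
concordance with ties counted ½. Chi-square association tests use no
continuity correction by default.

## Combined clinical + genomic model

Clinical covariates are encoded ordinally (grade 1–3; tumor size category
1–4 for <10, 10–20, 20–50, >50 mm) or binary (lymph node, p53, ER, PG).
ER and PG are offered to the selector even where they are expected to be
non-prognostic — selection, not curation, decides. Because PDS live in
[0, 1] and clinical codes on other scales, each block is re-standardized
feature-wise to mean 0 / sd 1 before stacking, so both face the same L1
penalty. Samples missing any offered clinical value are dropped from
combined training (complete-case; an imputation mode to the majority class
exists but is off by default). With an empty clinical block the combined fit
reduces exactly to the genomic-only code path.

## Validation machinery

*Sensitivity*: fractions 1/2, 1/4, 1/8, 1/16 of the pathway collection are
subsampled without replacement, 18 replicates each (per-replicate seeds
derived from the master seed by fixed offsets), and the full workflow is
re-run per replicate; a replicate selecting no feature is recorded flagged
with AUC 0.5 and p 1. *LOOCV*: by default only the PI threshold is
recomputed per left-out sample from the remaining samples' relapse ratio,
and p/AUC are computed on the remaining cohort — the fast variant matching
the headline workflow's logic; `refit=True` re-runs selection per fold and
is the statistically stricter option. *Gene ranking*: over the selected
pathways, each member gene gets count = number of selected pathways
containing it and weighted count = the sum of those pathways' hazard ratios;
genes are ranked by weighted count.

## Synthetic cohorts

`simulate_cohort` draws, per pathway, a latent deregulation score
t_p ~ N(0, 1) per sample; gene g in pathway p expresses
x = μ_g + a_g·t_p + ε with baselines μ_g ~ N(7, 1) (a log2-like scale),
loadings |a_g| ∈ [0.5, 1.5] with random sign, and ε ~ N(0, σ²). Relapse
times are exponential PH with linear predictor Σ_p γ_p t_p + γ_c·lymph_node
(inverse transform), censoring is independent uniform on (0, horizon).
Defaults — 300 patients, 40 pathways × 15 genes, 4 causal pathways with
γ = 1, σ = 0.5 — are the package's reference design; the baseline hazard
(0.35/year) and censoring horizon (15 years) were set once so that the
design censors ≈30% of subjects. A `population_seed` separate from the
sampling seed pins the truth (causal identity, loadings, baselines) so a
fresh cohort from the same population can be drawn for held-out evaluation.
Clinical covariates are drawn at fixed prevalences typical of mixed
node-positive/negative breast-cancer cohorts; only lymph node carries hazard
when γ_c ≠ 0.

What the generator does *not* emulate: probe-level structure, batch and
platform effects, correlated noise between pathways, overlapping true
functional units (annotation overlap is available as a knob but expression
effects stay single-membership), non-proportional hazards (a Weibull shape
deviation can be probed by transforming times), and informative censoring.
Passing tests therefore demonstrate that the pipeline recovers
pathway-structured PH signal under clean conditions and that its statistics
are calibrated — not that it will attain any particular performance on real
microarray cohorts.

## Problem sizes used in tests and the acceptance script

Unit and property tests use cohorts of 25–200 samples with 2–12 pathways.
The end-to-end recovery check runs the reference design over 20 seeds with
10×5-fold λ selection; the acceptance script runs the same design once plus
5 replicate recovery runs, threshold-only LOOCV, and one combined-model fit
(λ selection at 10 repeats). These sizes are the package's chosen defaults
for a deterministic, single-CPU verification run.

## Known limitations

- Without normal samples the PDS direction is a convention, not a biology;
  interpretation of "high PDS = deregulated" requires normals.
- The coordinate-descent engine supports Breslow ties only; Efron is
  available for likelihood evaluation and small unpenalized fits.
- Quantile normalization is the only built-in between-array method;
  cross-dataset batch correction is out of scope (datasets are processed
  independently).
- Absolute risk is not calibrated (no baseline-hazard estimation); the model
  ranks and dichotomizes.
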