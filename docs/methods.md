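# Methods

## Model and assumptions

For mRNA *j* with log-expression row **x**_j across *I* matched samples and
miRNA log-expression rows **z**_k, the model is

x_j = x_j⁰·1 + Σ_k c_jk β_jk z_k + ε_j,  β_jk ≤ 0,

where c_jk marks sequence-predicted putative pairs, β_jk is the amount of
down-regulation, x_j⁰ the expression expected without miRNA regulation, and
ε_j absorbs every other regulatory influence as noise. The assumptions this
encodes: (i) miRNAs are the only modelled regulators — the method can only
surface the most prominent interactions; (ii) miRNAs never up-regulate
their targets (hence the sign constraint); (iii) only pairs in the putative
mask can be recovered; (iv) log-expression is linear in the regulators'
log-expression. Inputs are assumed to be on a log scale already; ΔΔCt miRNA
data are negated on input (Ct falls as abundance rises), and a log2(x+1)
pre-transform is available for raw intensities. Each feature is
median-centered across samples before fitting, once, on the full data.

## Per-gene solver

Each gene is fit by minimizing ‖x − x⁰·1 − Σ β_k z_k‖² + λ Σ|β_k| subject
to β ≤ 0, intercept unpenalized. On the non-positive orthant the penalty is
linear (−λ Σ β_k), so the problem is a convex smooth quadratic over a cone
and any stationary point is the global optimum. The solver is cyclic
coordinate descent with the closed-form update
β_k ← min(0, (2 z_k·r_{−k} + λ) / (2‖z_k‖²)), intercept reset to the mean
residual each sweep, gram-matrix bookkeeping for O(K_j) updates per
coordinate. Convergence: largest coefficient change < `tol` (default 1e-8)
or relative objective change ≤ 1e-10, capped at `max_iter` = 10⁴ sweeps
(non-convergence returns the current iterate flagged, with a warning).
The plain-RSS convention (no ½ or 1/I factor) is used everywhere so the
penalty ceiling below is consistent with the solver.

Numerical details worth knowing:

* **Zero-variance regressors** (constant z_k) are collinear with the
  intercept and frozen at 0, both in the solver and in `lambda_max`.
* **Exact boundary.** `lambda_max` = max_k max(0, −2 z_k·(x − x̄)) is the
  KKT threshold at which β = 0 becomes optimal. It is computed with the
  same floating-point expressions the solver's first sweep uses, and
  doubling is exact in IEEE arithmetic, so `solve_gene(λ = lambda_max)`
  returns exactly zero coefficients, not just small ones. A constant x
  short-circuits to 0.
* **Collinearity.** Exact duplicates among the z_k make β non-unique; the
  objective value is still unique and is what the tests assert.
* **Unconstrained mode.** `nonpositive=False` gives standard LASSO via the
  two-sided soft threshold. It exists only for method comparison (the
  constrained fit is uniformly better on decoy designs); it is not a
  supported analysis mode.

## Penalty selection

λ_j = κ·Λ_j with one κ for all genes. The *global* schedule (default) uses
Λ_j = Λ = max_j λ_j^max, chosen so that κ = 1 shuts off every gene and all
per-gene solutions share one penalty, making scores comparable across
genes; the *local* schedule uses each gene's own ceiling. κ is selected by
leave-one-out cross-validation on the grid {1/10000, 1/100, 1/50, 1/20,
1/10, 1/5, 1/3, 1/2}: for each held-out sample the ceilings (and Λ) are
recomputed on the training samples — reusing full-data penalties would leak
the held-out sample — every gene is refit, and the held-out squared
prediction error is accumulated; the MSE denominator is the number of
(gene, sample) terms, J·I. Ties select the earliest grid value; the
procedure is fully deterministic. Median-centering is done once before CV,
not per fold: a deliberate, documented leakage that matches the original
preprocessing order. Within a fold the grid is traversed from large to
small κ with warm starts, which affects runtime only.

## Ranking, baseline and significance

Interactions with strictly negative β̂ are ranked ascending (strongest
down-regulation first), ties broken lexicographically by (mRNA, miRNA) for
reproducible output. The baseline ranks every masked pair by signed Pearson
correlation, ascending (signed r outperforms |r|, which cannot separate up-
from down-regulation; Spearman is available behind a flag as a
mutual-information proxy under normality). For selected coefficients an
unconstrained OLS refit of x_j on the intercept plus the selected miRNAs
gives per-coefficient t-tests with I − (s_j + 1) degrees of freedom.
Constrained refits were rejected because t statistics have no standard null
under inequality constraints. These p-values are conditional on the
selection step: they are descriptive, not calibrated unconditional error
rates. Exact fits are flagged `degenerate_fit`, collinear designs
`singular`, and genes with s_j + 1 ≥ I `insufficient_df`.

## Enrichment

For a ranking of the N putative interactions containing K_val validated
ones, the curve reports at each cutoff n the inclusive upper tail
P(X ≥ observed), X ~ Hypergeometric(N, K_val, n) (scipy's survival
function, stable in log space). By default the universe is restricted to
interactions whose mRNA has at least one validated target — genes that can
never contribute a success would otherwise dilute the test — and both N and
K_val are recomputed after restriction. The reported minimum p over n is
raw (no multiple-testing correction across cutoffs) and should be read as
an exploratory summary alongside the full curve; N_E_500 is the validated
count within the top 500 (clamped, with a warning, for shorter rankings).

## Synthetic data

The generator draws miRNA expression i.i.d. standard normal on the log
scale, samples per gene `putative_per_gene` mask entries of which
`true_per_gene` get β uniform in [−2, −0.5] (a strong-to-moderate effect
range whose per-gene signal SD is ≈1.9), adds Gaussian noise with σ = 0.3
by default (microarray-like log-scale noise, one-sixth of the signal SD),
and intercepts uniform in [4, 12] arbitrary log-units (irrelevant after
median-centering). Everything is reproducible from a single integer seed.
Two structured variants support method comparisons:

* **Two-condition blocks** — each miRNA is elevated (default shift 3.0) in
  one half of the samples; a gene regulated by one miRNA from each block
  has poor marginal correlation with either regulator while the joint fit
  explains it, the mechanism behind the correlation baseline's failures.
* **Positive decoys** (`generate_decoys`) — per gene, decoy miRNAs whose
  expression tracks the gene's regulated signal (positively correlated
  with the gene). Unconstrained LASSO chases them with positive
  coefficients and distorts the true negative ones; the constrained fit
  cannot, which is the basis of the constrained-vs-unconstrained
  comparison.

What the generator does *not* emulate: non-miRNA regulation (transcription
factors, copy number), measurement-platform batch structure, translational
repression without mRNA decay, and identifier-mapping noise. Passing the
recovery benchmarks therefore shows the estimator is correct and
well-behaved under its own model, not that real putative databases reach
any particular precision.

## Validation regimes and problem sizes

The acceptance checks run at sizes chosen to exercise the method fully
while keeping the whole suite fast on a single CPU:

* solver vs an exact support-enumeration oracle and the λ_max boundary:
  100 random problems, I ∈ [3,10], K ∈ [1,8];
* recovery: J = 200 genes, K = 50 miRNAs, I = 30 samples, 8 putative / 2
  true regulators per gene, σ = 0.3, LOOCV over the full grid; F1 measured
  in the top 2J interactions;
* decoy comparison: 20 replicates of J = 40, K = 12, I = 20 with 2 decoys
  per gene, both fits at the same fixed κ = 1/10 schedule (a per-mode CV
  would confound the sign-constraint comparison);
* LOOCV noise response: J = 25, K = 10, I = 12; noiseless data must select
  the smallest grid κ, data with σ = 4.0 (about twice the signal SD) should
  select κ ≥ 1/50;
* condition-specific comparison: 20 replicates of J = 30, K = 16, I = 24,
  shift 3.0, β ∈ [−2, −1], σ = 0.5, fixed κ = 1/10.

## Known limitations

* Per-gene fits ignore correlation between genes; no joint shrinkage.
* The selected-coefficient p-values are post-selection and anti-
  conservative.
* The global ceiling Λ ties every gene's penalty to the single strongest
  gene; a handful of extreme λ_j^max values can over-penalize the rest
  (the local schedule is the escape hatch).
* LOOCV cost scales as grid × samples × genes; for genome-scale inputs
  fix κ (e.g. 1/10) or subsample genes for tuning.
* No identifier translation: mRNA/miRNA IDs must already match across the
  three inputs.
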