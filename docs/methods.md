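# Methods

This note records the models, the estimators, the numerical choices and
the limits of the synthetic evidence, in the order the pipeline runs.

## Residual energy intake

REI is defined against the ordinary least-squares energy-sink model

    ME = β₀ + β₁·ECM + β₂·BW^0.75 + β₃·gain + β₄·loss + ε

fitted on all animal-days inside a days-in-milk window (default 3–100,
inclusive; records outside the window never enter the regression). The
gain/loss covariates are the positive and negative parts of the
day-to-day difference of a smoothed body-weight trajectory. Smoothing
is a centered rolling linear fit (default 15 days, configurable,
truncated at the series edges); without it, daily scale noise of a few
kilograms would dominate the tissue-change signal. An animal's REI is
the mean of its daily residuals — the aggregation from daily residuals
to one value per animal is a modelling choice here; the mean makes the
grand residual mean exactly zero and is invariant to adding a constant
to all intakes (absorbed by the intercept).

Efficiency groups are equal-thirds quantile groups of REI
(linear-interpolation quantiles; ties assigned to the lower group so
the grouping is deterministic). Low REI = efficient.

## Community profile

* Core filter: keep an ASV when its relative abundance strictly
  exceeds 0.1 % in at least ⌈n/2⌉ samples; relative abundances are
  recomputed on the kept set.
* Gini–Simpson 1 − Σp²; Simpson evenness (1/Σp²)/S with S the number
  of non-zero taxa of the sample.
* Bray–Curtis Σ|x−y|/Σ(x+y); per-sample divergence is the distance to
  the sample's group mean composition (a group median is available by
  flag; the choice of reference is a convention, the mean keeps the
  statistic differentiable in the data).
* PERMANOVA uses the squared-distance decomposition
  F = (SS_between/(g−1))/(SS_within/(n−g)). When the number of distinct
  label arrangements is small (≤ the requested permutation count) the
  permutation distribution is enumerated exactly; otherwise Monte-Carlo
  with the +1 correction bounds the attainable p at 1/(n_perm+1).
* Kruskal–Wallis is tie-corrected (scipy); pairwise two-sided rank-sum
  tests use the exact small-sample distribution where available.
* Jukes–Cantor distance −(3/4)·ln(1 − 4p/3) with the mismatch
  proportion computed over columns where both sequences have an
  unambiguous base; p ≥ 3/4 is reported as an error rather than a
  saturated value. UPGMA is size-weighted average linkage; node heights
  are half the merge distance so cophenetic distances reproduce an
  ultrametric input exactly.

## Archetype decomposition

The column-centered core relative-abundance table A_c is factorized as
X·Y with unconstrained scores and non-negative loadings. Fitting is
greedy sequential deflation: each component solves a rank-1 problem on
the current residual by alternating two closed-form steps
(y = [Rᵀx/‖x‖²]₊ then x = Ry/‖y‖²), initialized from the residual's
leading singular vector (both signs tried; extra random starts
optional), and the residual is deflated before the next component.

This fitting order is itself a design decision. A joint alternating
scheme over all components minimizes the same objective but leaves the
per-component split of X·Y unidentified: at the default rank
(min(n−1, 40)) it drifts into pairs of huge mutually-cancelling
components, and no meaningful per-component variance share can be
attached to them. Under sequential deflation the score step leaves each
residual orthogonal to its component, so the shares
‖x_j y_j‖²/‖A_c‖² are exact, non-negative, sum to at most one, and
coincide with PCA eigenvalue ratios whenever the underlying factors are
orthogonal. The price is that the k-component objective is only
greedily (not jointly) optimal; ranks are nested by construction.

Components with share > 1/n(ASV) are selected. Each selected score
column enters the predictor table after a Manly exponential transform
(e^{λx}−1)/λ, λ per column by profile (normal) likelihood over an
81-point grid on [−2, 2] (λ = 0 is the identity), then centering and
scaling to unit sd; Gini–Simpson and Simpson evenness are appended the
same way. Reconstruction from a component subset S is
column-means + X[:,S]·Y[S,:], clipped at zero and renormalized per row,
so reconstructed rows are always valid compositions.

## Boosted prediction

Squared-error gradient boosting over depth-limited CARTs, written from
first principles so every tie-break is specified: split candidates are
midpoints between consecutive distinct sorted values, ties resolved to
the lowest feature index then lowest threshold; leaves hold mean
residuals; no leaf smaller than `min_node`. The model is exactly
`base + η·Σ trees`, with row subsamples drawn without replacement from
a per-round counter-based substream of the model seed. No second-order
terms or shrinkage constants beyond η are used — with depth-2 trees and
η = 0.05 at this sample size, plain first-order boosting is the same
algorithm family at negligible difference. Defaults (26 rounds, depth
2, min 2 samples/node, η 0.05, 80 % row subsample, no column
subsampling) are the tuned operating point of the analysis this package
reproduces; the sequential tuner (initial depth probe 1–7 at η 0.1,
then two coordinate passes over η, column subsample, depth, row
subsample, min node size, each scored by minimum validation RMSE with
ties to the more regularized value) is available behind
`predict.tune: true`.

Data are split 8:1:1 (train = round(0.8n), validation = ⌊0.1n⌋, test =
remainder). Pearson r with zero-variance predictions is reported as
NaN with a warning, never silently zero.

## Interpreters

* TreeSHAP: exact Shapley values of the path-dependent (cover-weighted)
  value function. Because each depth-d tree uses at most 2^d−1
  features, exact subset enumeration per tree is cheap; features absent
  from a tree are dummy players. Additivity Σφ + base = prediction
  holds to machine precision and is asserted in tests against full
  2^p brute-force enumeration.
* ALE: quantile bins (default 40, reduced to the number of distinct
  values), local effects averaged over in-bin samples, accumulated and
  centered to zero count-weighted mean. Importance = max − min of the
  centered profile; profiles with range > 1.5 (model-output units) are
  highlighted.
* Surrogate tree: recursive partitioning of the model's predictions.
  At each node the predictor with the smallest permutation p-value of
  |Pearson r| is chosen and split at the SSE-optimal threshold; the
  p-value is multiplicity-adjusted as 1−(1−p)^m (the Bonferroni-style
  convention of conditional inference trees) so a pure-noise root is
  split only at about the nominal rate. Growth is breadth-first with at
  most five inner nodes; fidelity is R² between surrogate and model.

## Co-occurrence network

The REI-associated reconstruction (top five archetype predictors by
SHAP importance) is column-scaled and its correlation matrix fed to the
graphical lasso (block coordinate descent, off-diagonal L1 penalty,
numba-compiled inner loops with an incrementally maintained gradient).
The penalty runs over a 100-point log grid from 0.01·λ_max to λ_max
(λ_max = largest absolute off-diagonal correlation), warm-started from
large to small, and the fit minimizing

    EBIC(λ) = −2·loglik + |E|·log n + 4·γ·|E|·log p ,   γ = 0.5

is kept. Because a reconstruction from k components has rank k, its
correlation matrix is singular; rank-deficient inputs receive a 1e-3
shrinkage toward the identity (with a warning) so the likelihood is
well-defined along the whole path. Convergence tolerances (outer 50
sweeps at 1e-4 relative, inner 100 sweeps at 1e-6) were validated
against an independent ADMM optimizer (agreement ~1e-9 at p = 3) and
give the same EBIC selection as much tighter settings.

Hub scores are the principal eigenvector of the |partial correlation|
weighted adjacency, scaled to max 1 (for an undirected graph Kleinberg
hub = authority = eigenvector centrality); in disconnected graphs the
largest-eigenvalue component dominates, which is the intended "most
networked taxa" reading. Modules cut the UPGMA tree of the distance
1 − ρ at a quantile of the merge-height distribution
(deep_split 0..4 → 0.98, 0.95, 0.92, 0.88, 0.84 — higher deep_split
cuts lower and yields finer modules, mirroring the coarse-to-fine
behavior of hybrid dynamic tree cutting at desk scale); branches with
at least 10 leaves become modules, the rest is unassigned (label 0).
Per-ASV REI coefficients are cov(x, REI)/var(x) (slope with the
intercept fixed at the REI mean); module and hub associations use
Pearson r with the Student-t p-value t = r√(n−2)/√(1−r²).

## Metagenome statistics

TMM normalization follows the standard trimmed-mean-of-M-values recipe:
reference = sample with upper quartile closest to the mean upper
quartile; per sample, an inverse-variance weighted mean of log2 ratios
after trimming 30 % of log-ratios and 5 % of average intensities;
factors rescaled to geometric mean 1; normalized value =
count/(library × factor). Genes are kept when their total normalized
abundance reaches the 95 % linear-interpolation quantile of all totals
(the boundary gene is kept).

The directional test estimates the triple-ordering probability

    t̂_inc = (1/(n_L n_M n_H)) Σ [I(a<b)+½I(a=b)]·[I(b<c)+½I(b=c)]

over all (a,b,c) ∈ L×M×H (expectation 1/6 under a continuous
exchangeable null; ½-weights per tied pair, verified against O(n³)
enumeration), and t̂_dec with the roles of L and H exchanged — the
decreasing ordering is the mirror alternative of the increasing one.
P-values come from group-label permutations: exhaustive enumeration
when at most 10,000 distinct arrangements exist, otherwise Monte-Carlo
with the +1 correction (pipeline default 2,000 draws — at the desk
scale of ~1,000 genes this bounds q-values well below the 0.05
reporting threshold while keeping the stage in seconds; the function
default is 10,000). The per-gene p is the smaller directional p and
its direction label. The whole computation is vectorized across genes
and permutations through one pairwise-comparison tensor and BLAS
contractions.

BH adjustment is the standard step-up (statsmodels). CAZy families and
KOs are abundance sums over annotated member genes of the filtered
set; multi-family CAZy labels (e.g. "CBM48-GH13") are atomic. Pathway
completeness is |detected ∩ pathway| / |pathway| over the detected-KO
set. Enrichment of significant KOs (directional p ≤ 0.1) is the
hypergeometric upper tail P(X ≥ k) over the universe of detected KOs
present in any pathway — identical to the one-sided Fisher exact test
of the corresponding 2×2 table (asserted in tests) — BH-adjusted at
FDR 0.05.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions every downstream check runs under.

* Community: 87 animals × 400 ASVs; expected composition per sample is
  the convex blend (1−w)·baseline + w·normalize(X·Y) with w = 0.8, a
  fixed Dirichlet(0.3) baseline (long-tailed rank-abundance), five
  planted consortia of 20/20/15/15/10 ASVs with uniform(0.5, 1.5)
  non-negative loadings, lognormal(0, 0.8) consortium scores, and
  multinomial sampling at lognormal library sizes (median 25,000
  reads, σ = 0.3). About 130 ASVs survive the core filter. The blend
  weight doubles as the within-module co-abundance control.
* Phenotype: REI truth = standardized scores × component effects
  (5, −4, 3, 2.5, −2 MJ/d per sd; ‖effects‖ ≈ 7.8) plus an independent
  N(0, 7.8) animal effect, centered — total sd ≈ 11 MJ/d with roughly
  half the variance carried by the microbiome, so prediction is
  possible but bounded (max attainable r ≈ 0.7). Energy records use
  realistic sink coefficients (5.15 MJ/kg ECM, 0.6 MJ/kg^0.75, 34 and
  28 MJ/kg for gain and loss), a cubic early-loss/late-gain BW trend
  with AR(1) wiggle, a rising-to-plateau milk curve, and daily ME noise
  of 5 MJ/d over 98 days (DIM 3–100). The generator computes gain/loss
  with the same smoothing the fit applies, so a zero-noise cohort is
  exactly linear in the fitted design.
* Genes: Poisson-lognormal counts (within-group log-sd 0.6, per-sample
  depth lognormal σ = 0.2) for 1,000 genes over groups of 11/10/11
  samples (the metagenome subset scale). A planted 10 % of genes is
  shifted by 1 within-group sd per group step, direction random per
  gene; the planted genes are drawn from the upper half of baseline
  abundance and pathway KO sets are abundance-rank-weighted (weight ∝
  rank⁴), because downstream testing is restricted to the top 5 % most
  abundant genes — in real metagenomes, too, the testable differential
  signal lives in the abundant fraction. The planted enriched pathway
  takes the most abundant ordered genes outright. KO annotation covers
  80 % of genes (one KO per annotated gene, keeping gene- and KO-level
  signal aligned), CAZy 5 %.
* One cohort seed expands into independent per-stage substreams
  (`SeedSequence` spawn keys), so stages are individually reproducible
  and bit-identical across runs.

What the generator does **not** emulate: taxonomic phylogeny coupled to
co-occurrence, overdispersion beyond multinomial/Poisson-lognormal,
year or batch effects, shared KOs across many genes, umbrella-shaped
(non-monotone) group responses, and any coupling between the 16S cohort
and the gene matrix beyond the shared group design. Passing tests
therefore demonstrate correctness of the estimators and recoverability
of planted monotone/low-rank structure — not robustness to confounding
or compositional artifacts in real data.

## Known limitations

* Variance shares (and hence component selection) depend on the greedy
  fitting order; strongly correlated planted consortia can split or
  merge across components.
* EBIC on denoised (reconstructed) data tends to select the densest
  grid point — likelihood dominates once noise has been removed — so
  network sparsity is grid-floor-sensitive there; on full-rank data the
  optimum is interior (verified on planted sparse precisions).
* The hub-score/REI-coefficient correlation is a structural property of
  the data: the generator plants consortia of similar connectedness
  with mixed-sign effects, so unlike a real cohort it does not force a
  strong correlation between centrality and efficiency.
* The surrogate's permutation split selection is a simplification of
  full conditional inference (no score decomposition, |r| statistic
  only).
* Exhaustive PERMANOVA enumeration is limited to small designs; beyond
  that the +1-corrected Monte-Carlo p is conservative near its floor.
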