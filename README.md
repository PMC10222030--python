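# microrei

Rumen-microbiome analysis of dairy-cow feed efficiency: an end-to-end,
fully tested reimplementation of the statistical pipeline linking 16S
rumen community profiles and shotgun-metagenome gene abundances to
residual energy intake (REI) in lactating cows.

The package is aimed at quantitative microbiologists and animal
scientists who want each stage of such an analysis as a reusable,
seed-deterministic Python component — and at methodologists who want
every stage checkable against planted ground truth, which the built-in
synthetic cohort generator provides.

## What it computes

**Phenotype.** Daily metabolizable-energy intake is regressed on the
energy sinks by ordinary least squares,

    ME_t = β₀ + β₁·ECM_t + β₂·BW_t^0.75 + β₃·ΔBW⁺_t + β₄·ΔBW⁻_t + ε_t ,

where ΔBW⁺/ΔBW⁻ are piecewise gain/loss components of a smoothed
body-weight trajectory. The animal's REI is the mean of its daily
residuals over DIM 3–100; low REI marks an efficient animal. Animals
are cut into L/M/H efficiency tertiles.

**Community.** Core ASVs (relative abundance > 0.1 % in at least half
the samples), Gini–Simpson diversity 1 − Σp², Simpson evenness
(1/Σp²)/S, Bray–Curtis dissimilarities and per-sample divergence,
PERMANOVA, Kruskal–Wallis/Wilcoxon group tests, Jukes–Cantor distances
and UPGMA trees.

**Archetypes.** A generalized low-rank model A_c ≈ XY with non-negative
loadings Y, fitted by greedy rank-1 deflation; components explaining
more than 1/n(ASV) of the variance become predictors after a Manly
exponential transform, centering and scaling, joined by the two alpha
diversity indices.

**Prediction + interpretation.** Gradient-boosted regression trees
(default: 26 rounds, depth 2, η = 0.05, 80 % row subsampling) on an
8:1:1 train/validation/test split, with exact path-dependent TreeSHAP
values, accumulated-local-effects (ALE) profiles, and a ≤ 5-split
surrogate inference tree whose fidelity is reported as R².

**Co-occurrence network.** The table reconstructed from the strongly
REI-associated archetype components is analyzed with a sparse Gaussian
graphical model (graphical lasso tuned by the extended BIC, γ = 0.5);
partial-correlation edges give hub scores (principal eigenvector,
max = 1) and dendrogram modules (min 10 ASVs), each correlated with
REI.

**Metagenome.** TMM normalization, a 95 %-quantile high-abundance gene
filter, the directional generalized Mann–Whitney test of the stochastic
ordering F_L ≤st F_M ≤st F_H (triple-ordering probability estimate,
permutation p-values, Benjamini–Hochberg FDR), CAZy/KO aggregation,
KEGG pathway completeness and one-sided hypergeometric enrichment.

## Worked example

```python
import numpy as np
from microrei.simulate import CohortConfig, simulate_community, simulate_energy_records
from microrei.phenotype import fit_rei, assign_groups
from microrei.community import filter_core_asvs, alpha_diversity_table
from microrei.archetypes import ArchetypeGLRM, engineer_predictors
from microrei.boosting import GradientBoostedTreeRegressor, split_data, evaluate

cfg = CohortConfig(seed=42)               # 87 cows, 400 ASVs, 5 planted consortia
counts, truth = simulate_community(cfg)
records = simulate_energy_records(truth, cfg)

res = fit_rei(records, dim_window=(3, 100))
groups = assign_groups(res.rei)
r = np.corrcoef(res.rei.to_numpy(), truth.rei_true)[0, 1]
print(f"REI recovery r = {r:.3f}; group sizes = {groups.value_counts().to_dict()}")

core = filter_core_asvs(counts)
glrm = ArchetypeGLRM().fit(core.relative)
print(f"selected components: {len(glrm.selected_)} "
      f"({100 * glrm.variance_shares_[glrm.selected_].sum():.1f}% of variance)")

predictors, _ = engineer_predictors(glrm, alpha_diversity_table(core.relative))
split = split_data(len(predictors), seed=42)
X, y = predictors.to_numpy(), res.rei.to_numpy()
model = GradientBoostedTreeRegressor().fit(X[split.train], y[split.train])
print(evaluate(model, X, y, split).to_string(index=False))
```

prints

```
REI recovery r = 0.994; group sizes = {'M': 29, 'H': 29, 'L': 29}
selected components: 5 (99.1% of variance)
    subset  n  pearson_r      rmse
     train 70   0.804766  7.234196
validation  8   0.442867 11.925626
      test  9   0.491941 12.954798
```

The phenotype stage recovers the planted REI almost perfectly because
daily noise (5 MJ/d) averages out over 98 records per cow. The five
selected archetype components are the five planted consortia. The
boosted model's held-out correlations (~0.44–0.49) reflect that only
about half of the REI variance is carried by the microbiome under the
default generator settings — the rest is planted as microbe-independent
animal variation and is not predictable from the community.

## Command-line pipeline

Every stage is also a CLI subcommand operating on a shared run
directory:

```bash
microrei all --outdir run1 --seed 7          # simulate → ... → report
microrei network --outdir run1               # re-run a single stage
```

Stages read their upstream TSV/JSON files, write results plus a
`log_<stage>.json` with versions, seed and parameters, and are
bit-reproducible for a fixed seed. Configuration is a YAML document
merged over `microrei.io.default_config()`.

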