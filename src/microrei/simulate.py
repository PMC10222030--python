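"""Synthetic dairy-cow cohorts with known ground truth.

Three generators emulate the data structures the analysis pipeline
consumes, each with planted, recoverable signal:

* :func:`simulate_community` — a compositional ASV count table whose
  expected composition is a convex blend of a fixed baseline and a
  non-negative low-rank term ``X_true @ Y_true`` (consortium scores times
  non-negative loadings), sampled multinomially at lognormal library
  sizes.  Consortium components load on planted co-abundance modules.
* :func:`simulate_energy_records` — daily energy records where ME intake
  is exactly linear in the energy sinks plus the planted per-animal REI
  and iid daily noise, so the REI fit is checkable against truth.
* :func:`simulate_gene_matrix` — a gene-by-sample count matrix over three
  ordered groups (L < M < H) with a planted fraction of stochastically
  ordered genes, KO/CAZy annotation maps and pathways that over-sample
  ordered genes.

One cohort seed is expanded into independent per-stage substreams via
``numpy.random.SeedSequence`` spawn keys, so each stage is individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotype import derive_bw_change

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "simulate_community",
    "simulate_energy_records",
    "simulate_gene_matrix",
]

#: Default energy-sink coefficients (MJ/d per unit sink):
#: intercept, ECM (kg/d), metabolic BW (kg^0.75), BW gain (kg/d), BW loss (kg/d).
DEFAULT_ENERGY_BETAS = (10.0, 5.15, 0.60, 34.0, 28.0)


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror a realistic primiparous-cow 16S cohort: 87 animals,
    400 ASVs (of which a core of roughly 80 survives the abundance
    filter), five planted consortia, REI spread of about 11 MJ/d with
    roughly half the REI variance attributable to the microbial
    components, and 98 daily records spanning DIM 3-100.
    """

    n_animals: int = 87
    n_asvs: int = 400
    n_components: int = 5                      # true rank of the planted term
    module_sizes: tuple[int, ...] = (20, 20, 15, 15, 10)
    within_module_assoc: float = 0.8           # blend weight of the low-rank term
    component_effects: tuple[float, ...] | None = None  # MJ/d per sd; None = auto
    rei_independent_sd: float = 7.8            # REI variance not carried by microbes
    library_size_mean: float = 25_000.0        # reads (lognormal median)
    library_size_sd: float = 0.3               # lognormal sigma, log-reads
    noise_sd: float = 5.0                      # daily ME noise, MJ/d
    n_days: int = 98
    energy_betas: tuple[float, ...] = DEFAULT_ENERGY_BETAS
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_animals, self.n_asvs, self.n_components, self.n_days) <= 0:
            raise ConfigError("all counts must be positive")
        if any(m <= 0 for m in self.module_sizes):
            raise ConfigError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_asvs:
            raise ConfigError(
                f"sum of module sizes {sum(self.module_sizes)} exceeds n_asvs {self.n_asvs}"
            )
        if self.n_components < len(self.module_sizes):
            raise ConfigError("n_components must be >= number of planted modules")
        if not 0 <= self.within_module_assoc < 1:
            raise ConfigError("within_module_assoc must lie in [0, 1)")
        if self.component_effects is None:
            base = [5.0, -4.0, 3.0, 2.5, -2.0]
            while len(base) < self.n_components:
                base.append(1.5 if len(base) % 2 == 0 else -1.5)
            self.component_effects = tuple(base[: self.n_components])
        if len(self.component_effects) != self.n_components:
            raise ConfigError("component_effects must have length n_components")
        if len(self.energy_betas) != 5:
            raise ConfigError("energy_betas must be (b0, b_ecm, b_mbw, b_gain, b_loss)")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent generator for one pipeline stage (0=community, ...)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic cohort."""

    X_true: np.ndarray                    # n_animals x n_components scores
    Y_true: np.ndarray                    # n_components x n_asvs, non-negative
    module_labels: np.ndarray             # per-ASV module id, 0 = background
    rei_true: np.ndarray                  # per-animal REI, MJ/d, mean 0
    energy_betas: np.ndarray              # coefficients of the intake model
    ordered_gene_ids: set[str] = field(default_factory=set)
    enriched_pathway_ids: set[str] = field(default_factory=set)


def simulate_community(config: CohortConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw an ASV count table with planted low-rank consortium structure.

    The expected composition of sample i is
    ``(1 - w) * baseline + w * normalize(X_i @ Y)`` with ``w`` the
    within-module association weight; counts are multinomial at a
    lognormal library size.  Returns (samples x ASVs counts, truth).
    """
    rng = config.rng(0)
    n, p, k = config.n_animals, config.n_asvs, config.n_components
    m = len(config.module_sizes)

    module_labels = np.zeros(p, dtype=int)
    start = 0
    for j, size in enumerate(config.module_sizes, start=1):
        module_labels[start : start + size] = j
        start += size

    # fixed baseline composition; Dirichlet(0.3) gives a realistic
    # long-tailed rank-abundance curve
    baseline = rng.dirichlet(np.full(p, 0.3))

    # non-negative loadings: one component per planted module, extra
    # components (if any) load on random background ASVs
    Y = np.zeros((k, p))
    for j in range(m):
        members = module_labels == j + 1
        Y[j, members] = rng.uniform(0.5, 1.5, size=members.sum())
    background = np.flatnonzero(module_labels == 0)
    for j in range(m, k):
        size = max(5, int(np.mean(config.module_sizes)))
        chosen = rng.choice(background, size=min(size, background.size), replace=False)
        Y[j, chosen] = rng.uniform(0.5, 1.5, size=chosen.size)
    Y_rows = Y / Y.sum(axis=1, keepdims=True)

    # skewed non-negative consortium scores
    X = rng.lognormal(mean=0.0, sigma=0.8, size=(n, k))

    low_rank = X @ Y_rows
    low_rank = low_rank / low_rank.sum(axis=1, keepdims=True)
    w = config.within_module_assoc
    probs = (1.0 - w) * baseline[None, :] + w * low_rank
    # exact simplex per sample before sampling
    probs = probs / probs.sum(axis=1, keepdims=True)

    libs = rng.lognormal(np.log(config.library_size_mean), config.library_size_sd, n)
    libs = np.maximum(libs.round().astype(int), 1000)
    counts = np.vstack([rng.multinomial(libs[i], probs[i]) for i in range(n)])

    # REI truth: standardized scores times component effects (MJ/d per sd)
    # plus a microbe-independent animal effect; centered to mean 0
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    rei = Z @ np.asarray(config.component_effects)
    rei = rei + rng.normal(0.0, config.rei_independent_sd, size=n)
    rei = rei - rei.mean()

    samples = [f"cow{i + 1:03d}" for i in range(n)]
    asvs = [f"ASV{j + 1:04d}" for j in range(p)]
    table = pd.DataFrame(counts, index=samples, columns=asvs)
    truth = SyntheticTruth(
        X_true=X,
        Y_true=Y,
        module_labels=module_labels,
        rei_true=rei,
        energy_betas=np.asarray(config.energy_betas),
    )
    return table, truth


def simulate_energy_records(
    truth: SyntheticTruth, config: CohortConfig
) -> pd.DataFrame:
    """Daily energy records consistent with the planted REI.

    ME intake is exactly ``b0 + b1*ECM + b2*BW^0.75 + b3*gain + b4*loss
    + rei_true + N(0, noise_sd)`` where gain/loss come from the same
    smoothed-trajectory differencing the REI fit applies, so a zero-noise
    cohort is recovered exactly.  BW follows a cubic lactation trend
    (early loss, later gain) plus an AR(1) wiggle; ECM follows a
    rising-to-plateau curve.
    """
    rng = config.rng(1)
    b0, b_ecm, b_mbw, b_gain, b_loss = truth.energy_betas
    n_days = config.n_days
    dim = np.arange(3, 3 + n_days)
    rows = []
    for i in range(len(truth.rei_true)):
        base_bw = rng.normal(620.0, 45.0)
        s = (dim - dim[0]) / max(n_days - 1, 1)
        a1, a2, a3 = rng.normal(-25, 8), rng.normal(40, 10), rng.normal(0, 8)
        wiggle = np.empty(n_days)
        wiggle[0] = rng.normal(0, 2)
        eps = rng.normal(0, 2.0, n_days)
        for t in range(1, n_days):
            wiggle[t] = 0.7 * wiggle[t - 1] + eps[t]
        bw = base_bw + a1 * s + a2 * s**2 + a3 * s**3 + wiggle

        peak = rng.normal(32.0, 4.0)
        ecm = peak * (1.0 - 0.55 * np.exp(-0.07 * dim)) + rng.normal(0, 1.2, n_days)
        ecm = np.maximum(ecm, 0.1)

        gain, loss = derive_bw_change(bw, window=15)
        me = (
            b0
            + b_ecm * ecm
            + b_mbw * bw**0.75
            + b_gain * gain
            + b_loss * loss
            + truth.rei_true[i]
            + rng.normal(0.0, config.noise_sd, n_days)
        )
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": f"cow{i + 1:03d}",
                    "dim": dim,
                    "ecm": ecm,
                    "bw": bw,
                    "me_intake": me,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


_CAZY_FAMILIES = (
    "GH3 GH5 GH8 GH13 GH18 GH26 GH31 GH43 GH57 GH94 GH95 GT2 GT4 GT5 GT19 "
    "GT20 GT35 GT39 GT51 GT66 CE1 CE10 PL8 PL11 CBM48-GH13 GH31-GH97 GT2-GT4"
).split()


def simulate_gene_matrix(
    n_genes: int = 1000,
    group_sizes: tuple[int, int, int] = (11, 10, 11),
    effect: float = 1.0,
    ordered_fraction: float = 0.1,
    pathway_spec: dict | None = None,
    seed: int = 0,
    ko_coverage: float = 0.8,
    cazy_coverage: float = 0.05,
    log_sd: float = 0.6,
    depth_sd: float = 0.2,
    da_abundance_quantile: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series, dict, SyntheticTruth]:
    """Gene counts over three ordered groups with planted ordered genes.

    A planted fraction of genes has lognormal means shifted by
    ``effect`` within-group log-sd units per group step (direction
    random per gene); the rest are exchangeable across groups.  Counts
    are Poisson-lognormal with per-sample depth factors.

    Ordered genes are drawn from the genes above the
    ``da_abundance_quantile`` of baseline abundance (falling back to
    all genes when the planted fraction exceeds that pool), and pathway
    KO sets are sampled with abundance-rank weights: downstream testing
    is restricted to highly abundant genes, so, as in real metagenomes,
    the detectable differential signal sits in the abundant fraction.

    ``pathway_spec`` keys: ``n_pathways`` (default 20), ``kos_per_pathway``
    (default 12), ``enriched`` — a mapping pathway_id -> fraction of its
    KOs drawn from ordered genes (default plants one pathway at 0.8).

    Returns ``(counts genes x samples, group labels per sample,
    annotation maps, truth)``; annotation maps are ``gene2ko``,
    ``gene2cazy`` and ``pathway2kos``.
    """
    if not 0.0 <= ordered_fraction <= 1.0:
        raise ConfigError("ordered_fraction must lie in [0, 1]")
    if len(group_sizes) != 3 or any(g < 2 for g in group_sizes):
        raise ConfigError("three group sizes of at least 2 are required")
    spec = {"n_pathways": 20, "kos_per_pathway": 12, "enriched": {"pw_planted": 0.8}}
    if pathway_spec:
        spec.update(pathway_spec)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    n_samples = sum(group_sizes)
    groups = pd.Series(
        np.repeat(["L", "M", "H"], group_sizes),
        index=[f"cow{i + 1:03d}" for i in range(n_samples)],
        name="group",
    )
    group_step = np.repeat([-1.0, 0.0, 1.0], group_sizes)

    genes = [f"gene{g + 1:05d}" for g in range(n_genes)]
    log_mu = rng.normal(3.0, 1.5, size=n_genes)

    n_ordered = int(round(ordered_fraction * n_genes))
    pool = np.flatnonzero(log_mu >= np.quantile(log_mu, da_abundance_quantile))
    if n_ordered > pool.size:
        pool = np.arange(n_genes)
    ordered_idx = rng.choice(pool, size=n_ordered, replace=False)
    direction = np.zeros(n_genes)
    direction[ordered_idx] = rng.choice([-1.0, 1.0], size=n_ordered)
    depth = rng.lognormal(0.0, depth_sd, size=n_samples)
    shift = direction[:, None] * effect * log_sd * group_step[None, :]
    log_lam = (
        log_mu[:, None]
        + shift
        + rng.normal(0.0, log_sd, size=(n_genes, n_samples))
        + np.log(depth)[None, :]
    )
    counts = rng.poisson(np.exp(log_lam))
    table = pd.DataFrame(counts, index=genes, columns=groups.index)

    # annotations: one KO per annotated gene (keeps gene- and KO-level
    # planted signal aligned), a sparse CAZy family assignment
    n_ko = int(round(ko_coverage * n_genes))
    ko_genes = rng.choice(n_genes, size=n_ko, replace=False)
    gene2ko = {genes[g]: f"K{g + 1:05d}" for g in sorted(ko_genes)}
    n_cazy = int(round(cazy_coverage * n_genes))
    cazy_genes = rng.choice(n_genes, size=n_cazy, replace=False)
    gene2cazy = {
        genes[g]: _CAZY_FAMILIES[rng.integers(len(_CAZY_FAMILIES))]
        for g in sorted(cazy_genes)
    }

    ordered_set = {genes[g] for g in ordered_idx}
    ordered_kos = sorted(ko for g, ko in gene2ko.items() if g in ordered_set)
    null_kos = sorted(ko for g, ko in gene2ko.items() if g not in ordered_set)

    gene_pos = {g: i for i, g in enumerate(genes)}
    ranks = np.empty(n_genes)
    ranks[np.argsort(log_mu)] = np.arange(1, n_genes + 1)
    ko_of = {v: k for k, v in gene2ko.items()}

    def _weighted(kos: list[str], k: int, power: int = 4) -> list[str]:
        if k <= 0 or not kos:
            return []
        w = np.array([ranks[gene_pos[ko_of[ko]]] ** power for ko in kos])
        idx = rng.choice(len(kos), size=min(k, len(kos)), replace=False, p=w / w.sum())
        return [kos[i] for i in idx]

    pathway2kos: dict[str, set[str]] = {}
    size = int(spec["kos_per_pathway"])
    for pid, frac in dict(spec["enriched"]).items():
        n_ord = min(int(round(frac * size)), len(ordered_kos))
        # the planted pathway takes the most abundant ordered genes so its
        # differential signal survives the high-abundance filter downstream
        by_abundance = sorted(
            ordered_kos, key=lambda ko: -log_mu[gene_pos[ko_of[ko]]]
        )
        pathway2kos[pid] = set(
            by_abundance[:n_ord] + _weighted(null_kos, size - n_ord)
        )
    # background pathways: abundance-rank-weighted KO sampling, since
    # real pathways are dominated by common core-metabolic genes
    all_kos = sorted(gene2ko.values())
    for j in range(int(spec["n_pathways"])):
        pathway2kos[f"pw{j + 1:03d}"] = set(_weighted(all_kos, size))

    annotation = {"gene2ko": gene2ko, "gene2cazy": gene2cazy, "pathway2kos": pathway2kos}
    truth = SyntheticTruth(
        X_true=np.empty((0, 0)),
        Y_true=np.empty((0, 0)),
        module_labels=np.empty(0, dtype=int),
        rei_true=np.empty(0),
        energy_betas=np.asarray(DEFAULT_ENERGY_BETAS),
        ordered_gene_ids=ordered_set,
        enriched_pathway_ids=set(spec["enriched"]),
    )
    return table, groups, annotation, truth
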