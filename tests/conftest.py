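import numpy as np
import pytest

from microrei import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-animal cohort with planted consortium structure, reused
    across read-only tests."""
    cfg = sim.CohortConfig(
        n_animals=40,
        n_asvs=120,
        n_components=3,
        module_sizes=(15, 12, 10),
        component_effects=(5.0, -4.0, 3.0),
        seed=11,
    )
    counts, truth = sim.simulate_community(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    """The REI-recovery study condition: n=100, daily noise 5 MJ/d,
    planted REI spread about 10 MJ/d."""
    cfg = sim.CohortConfig(
        n_animals=100,
        n_asvs=120,
        n_components=3,
        module_sizes=(15, 12, 10),
        component_effects=(5.0, -4.0, 3.0),
        rei_independent_sd=7.8,
        noise_sd=5.0,
        seed=7,
    )
    counts, truth = sim.simulate_community(cfg)
    records = sim.simulate_energy_records(truth, cfg)
    return cfg, truth, records


@pytest.fixture(scope="session")
def gene_cohort():
    table, groups, annotation, truth = sim.simulate_gene_matrix(
        n_genes=400, effect=1.5, ordered_fraction=0.15, seed=5
    )
    return table, groups, annotation, truth


def planted_precision(p=20, n_edges=15, seed=3):
    """A sparse partial-correlation structure and samples drawn from it."""
    rng = np.random.default_rng(seed)
    Om = np.eye(p)
    for _ in range(n_edges):
        i, j = rng.choice(p, 2, replace=False)
        Om[i, j] = Om[j, i] = 0.25
    w = np.linalg.eigvalsh(Om).min()
    if w < 0.1:
        Om += (0.1 - w) * np.eye(p)
    Sig = np.linalg.inv(Om)
    d = np.sqrt(np.diag(Sig))
    Sig = Sig / np.outer(d, d)
    true_precision = np.linalg.inv(Sig)
    return Sig, true_precision, rng
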