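import numpy as np
import pytest

from cycleclass import (
    NormalizedMatrix,
    SimulationConfig,
    normalize_log,
    select_hvg,
    simulate_cycle_counts,
)


@pytest.fixture(scope="session")
def small_sim():
    """A modest cyclic simulation shared across tests (500 cells)."""
    cfg = SimulationConfig(
        n_cells=500, n_genes=800, markers_per_phase=50, seed=11
    )
    return simulate_cycle_counts(cfg)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    return normalize_log(small_sim.counts)


@pytest.fixture(scope="session")
def small_hvg(small_norm):
    return select_hvg(small_norm, 300)


def make_norm(values, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    """Wrap a raw array as a NormalizedMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids)


@pytest.fixture(scope="session")
def separable_dataset():
    """Two perfectly separated classes: disjoint marker support, huge effect."""
    rng = np.random.default_rng(42)
    n_per, n_genes = 100, 60
    base = np.abs(rng.normal(1.0, 0.2, size=(n_genes, 2 * n_per)))
    base[:20, :n_per] += 8.0  # class A markers
    base[20:40, n_per:] += 8.0  # class B markers
    norm = make_norm(base)
    labels = np.array(["A"] * n_per + ["B"] * n_per, dtype=object)
    return norm, labels
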