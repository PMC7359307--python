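import numpy as np
import pytest

from selsweep import SimulationConfig, simulate_neutral_panel, simulate_split_populations, simulate_sweep


@pytest.fixture(scope="session")
def small_neutral_panels():
    """Ten small neutral panels (Ne=50, 100 kb) for pooled-spectrum checks."""
    cfg = dict(pop_size=50, seq_length=100_000, mutation_rate=2e-6, n_diploids_per_pop=20)
    return [
        simulate_neutral_panel(SimulationConfig(seed=100 + s, **cfg)) for s in range(10)
    ]


@pytest.fixture(scope="session")
def small_sweep():
    """One modest sweep panel with truth, reused by several unit tests."""
    cfg = SimulationConfig(
        pop_size=100, seq_length=500_000, mutation_rate=2e-6,
        n_diploids_per_pop=40, sweep_site=250_000, selection_coeff=0.5,
        sweep_target_freq=0.75, seed=4,
    )
    return simulate_sweep(cfg)


@pytest.fixture(scope="session")
def split3_panels():
    """Five three-population split panels for structure checks."""
    cfg = dict(
        n_pops=3, pop_size=100, seq_length=300_000, mutation_rate=2e-6,
        n_diploids_per_pop=30, split_generations=20,
    )
    return [
        simulate_split_populations(SimulationConfig(seed=300 + s, **cfg))
        for s in range(5)
    ]


def maf_filter(panel, min_maf=0.05):
    """QC-grade per-panel MAF filter used before haplotype scans."""
    f = panel.derived_freq()
    return panel.subset_sites(np.minimum(f, 1 - f) >= min_maf)
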