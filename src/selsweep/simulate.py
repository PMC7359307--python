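"""Forward Wright-Fisher simulation of phased SNP panels.

Generates the three panel flavours the downstream analyses are exercised on:

* neutral single-population panels,
* panels carrying a hard selective sweep (with known ground truth),
* multi-population panels produced by splitting one ancestral pool into
  isolated daughter populations.

The model is a discrete-generation forward Wright-Fisher process on binary
haplotypes under the infinite-sites approximation: each generation every
diploid offspring draws a parent (fitness-weighted under selection) for each
of its two gametes, each gamete is a single-crossover recombinant of the
parent's two haplotypes with probability ``min(1, r * L)``, and
``Poisson(2 N L mu)`` new derived mutations land at previously unused
positions.  The founder allele is ancestral by construction, so simulated
panels always know allele polarity.

Defaults emulate a small farmed-fish strain panel: Ne = 200,
mu = 1.25e-6 /bp/gen and L = 1 Mb give an equilibrium nucleotide diversity
around 8.6e-4 after the 4N-generation burn-in, and r = 1e-6 /bp/gen gives
r^2 decaying to background over well under 100 kb.  A split of ~18
generations at Ne = 200 yields pairwise FST near 0.045.  These magnitudes
match typical resequencing panels of recently diverged aquaculture strains.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "SimulationConfig",
    "SweepTruth",
    "SimulationFailure",
    "InvalidConfig",
    "simulate_neutral_panel",
    "simulate_sweep",
    "simulate_split_populations",
    "write_vcf",
]


class InvalidConfig(ValueError):
    """Raised for inconsistent simulation parameters."""


class SimulationFailure(RuntimeError):
    """Raised when a conditioned sweep cannot be completed (restart cap hit)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Wright-Fisher run (one chromosome).

    All rates are per generation; ``mutation_rate`` and
    ``recombination_rate`` are per base pair.  Desk-scale defaults
    (N <= 500, L <= 2 Mb) are assumed throughout.
    """

    n_pops: int = 1
    n_diploids_per_pop: int = 60
    seq_length: int = 1_000_000
    mutation_rate: float = 1.25e-6
    recombination_rate: float = 1e-6
    pop_size: int = 200
    split_generations: int = 0
    sweep_site: int | None = None
    selection_coeff: float = 0.0
    sweep_pop: int = 0
    sweep_target_freq: float = 0.8
    max_restarts: int = 1000
    burn_in_factor: int = 4
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size <= 0 or self.seq_length < 1:
            raise InvalidConfig("pop_size and seq_length must be positive")
        if self.n_pops < 1 or self.n_diploids_per_pop < 1:
            raise InvalidConfig("need at least one population and one diploid")
        if self.n_diploids_per_pop > self.pop_size:
            raise InvalidConfig("cannot sample more diploids than pop_size")
        for name in ("mutation_rate", "recombination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfig(f"{name} must lie in [0, 1]")
        if self.selection_coeff < 0:
            raise InvalidConfig("selection_coeff must be >= 0")
        if self.split_generations < 0:
            raise InvalidConfig("split_generations must be >= 0")
        if self.sweep_site is not None and not (1 <= self.sweep_site <= self.seq_length):
            raise InvalidConfig("sweep_site must lie within [1, seq_length]")
        if not 0.0 < self.sweep_target_freq <= 1.0:
            raise InvalidConfig("sweep_target_freq must lie in (0, 1]")
        if not 0 <= self.sweep_pop < self.n_pops:
            raise InvalidConfig("sweep_pop out of range")


@dataclass(frozen=True)
class SweepTruth:
    """Ground truth of a simulated sweep."""

    position: int
    final_freq: float
    generations: int
    restarts: int


_POP_LABELS = list(string.ascii_uppercase)


def _pop_label(i: int) -> str:
    # A, B, ... Z, P26, P27, ...
    return _POP_LABELS[i] if i < 26 else f"P{i}"


class _Population:
    """Mutable Wright-Fisher state: 2N haplotypes over segregating sites."""

    __slots__ = ("H", "positions")

    def __init__(self, H: np.ndarray, positions: np.ndarray):
        self.H = H  # (2N, m) uint8
        self.positions = positions  # (m,) int64, strictly increasing

    def copy(self) -> "_Population":
        return _Population(self.H.copy(), self.positions.copy())

    def freq_at(self, position: int) -> float:
        j = np.searchsorted(self.positions, position)
        if j >= self.positions.size or self.positions[j] != position:
            return 0.0
        return float(self.H[:, j].mean())


def _sample_parents(rng: np.random.Generator, n_off: int, weights: np.ndarray) -> np.ndarray:
    """Inverse-CDF parent sampling; uniform weights reproduce the neutral path."""
    cum = np.cumsum(weights)
    cum /= cum[-1]
    return np.searchsorted(cum, rng.random(n_off), side="right").astype(np.int64)


def _advance(
    pop: _Population,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    weights: np.ndarray,
) -> None:
    """One Wright-Fisher generation, in place."""
    N = pop.H.shape[0] // 2
    L = cfg.seq_length
    n_gam = 2 * N

    parents = _sample_parents(rng, n_gam, weights)
    which = rng.integers(0, 2, size=n_gam)
    cross = rng.random(n_gam) < min(1.0, cfg.recombination_rate * L)
    breakpts = rng.integers(1, L + 1, size=n_gam)

    first = pop.H[2 * parents + which]
    second = pop.H[2 * parents + 1 - which]
    # gamete takes `first` up to the breakpoint, `second` beyond it
    take_second = cross[:, None] & (pop.positions[None, :] > breakpts[:, None])
    H_new = np.where(take_second, second, first)

    # new mutations at unused positions (infinite-sites approximation)
    n_new = rng.poisson(n_gam * L * cfg.mutation_rate)
    if n_new:
        new_pos = rng.integers(1, L + 1, size=n_new)
        carriers = rng.integers(0, n_gam, size=n_new)
        new_pos, keep_idx = np.unique(new_pos, return_index=True)
        carriers = carriers[keep_idx]
        fresh = ~np.isin(new_pos, pop.positions)
        new_pos, carriers = new_pos[fresh], carriers[fresh]
        if new_pos.size:
            cols = np.zeros((n_gam, new_pos.size), dtype=np.uint8)
            cols[carriers, np.arange(new_pos.size)] = 1
            insert_at = np.searchsorted(pop.positions, new_pos)
            pop.positions = np.insert(pop.positions, insert_at, new_pos)
            H_new = np.insert(H_new, insert_at, cols, axis=1)
    pop.H = np.ascontiguousarray(H_new, dtype=np.uint8)


def _prune_monomorphic(pop: _Population, keep_positions: np.ndarray | None = None) -> None:
    counts = pop.H.sum(axis=0)
    seg = (counts > 0) & (counts < pop.H.shape[0])
    if keep_positions is not None and keep_positions.size:
        seg |= np.isin(pop.positions, keep_positions)
    if not seg.all():
        pop.H = np.ascontiguousarray(pop.H[:, seg])
        pop.positions = pop.positions[seg]


def _sweep_weights(pop: _Population, site: int, s: float) -> np.ndarray | None:
    """Multiplicative fitness (1+s) per derived copy; None if allele lost."""
    j = np.searchsorted(pop.positions, site)
    if j >= pop.positions.size or pop.positions[j] != site:
        return None
    dosage = pop.H[0::2, j].astype(np.float64) + pop.H[1::2, j]
    if dosage.sum() == 0:
        return None
    return (1.0 + s) ** dosage


def _burn_in(cfg: SimulationConfig, rng: np.random.Generator) -> _Population:
    n_gam = 2 * cfg.pop_size
    pop = _Population(
        np.zeros((n_gam, 0), dtype=np.uint8), np.empty(0, dtype=np.int64)
    )
    uniform = np.ones(cfg.pop_size)
    for _ in range(cfg.burn_in_factor * cfg.pop_size):
        _advance(pop, cfg, rng, uniform)
        _prune_monomorphic(pop)
    return pop


def _emit_panel(
    cfg: SimulationConfig,
    pops: list[_Population],
    rng: np.random.Generator,
) -> HaplotypePanel:
    """Sample diploids per population and keep sites segregating in the sample."""
    all_positions = pops[0].positions
    for p in pops[1:]:
        all_positions = np.union1d(all_positions, p.positions)

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    population_of: dict[str, str] = {}
    for k, pop in enumerate(pops):
        N = pop.H.shape[0] // 2
        chosen = rng.choice(N, size=cfg.n_diploids_per_pop, replace=False)
        chosen.sort()
        rows = np.empty(2 * chosen.size, dtype=np.int64)
        rows[0::2] = 2 * chosen
        rows[1::2] = 2 * chosen + 1
        # expand this population's columns onto the union of positions
        block = np.zeros((rows.size, all_positions.size), dtype=np.uint8)
        col_idx = np.searchsorted(all_positions, pop.positions)
        block[:, col_idx] = pop.H[rows]
        blocks.append(block)
        label = _pop_label(k)
        for i in range(cfg.n_diploids_per_pop):
            sid = f"{label}_{i:03d}"
            sample_ids.append(sid)
            population_of[sid] = label

    alleles = np.vstack(blocks)
    counts = alleles.sum(axis=0)
    seg = (counts > 0) & (counts < alleles.shape[0])
    return HaplotypePanel(
        alleles=alleles[:, seg],
        positions=all_positions[seg],
        chrom_ids=np.asarray([cfg.chrom] * int(seg.sum()), dtype=object),
        sample_ids=sample_ids,
        population_of=population_of,
        ancestral_known=np.ones(int(seg.sum()), dtype=bool),
        chrom_lengths={cfg.chrom: cfg.seq_length},
    )


def simulate_neutral_panel(config: SimulationConfig) -> HaplotypePanel:
    """Single-population neutral panel (burn-in of >= 4N generations)."""
    if config.selection_coeff != 0:
        raise InvalidConfig("neutral simulation requires selection_coeff = 0")
    if config.n_pops != 1 and config.split_generations != 0:
        raise InvalidConfig("use simulate_split_populations for split designs")
    ss = np.random.SeedSequence(config.seed)
    burn_seed, emit_seed = ss.spawn(2)
    pop = _burn_in(config, np.random.default_rng(burn_seed))
    return _emit_panel(config, [pop], np.random.default_rng(emit_seed))


def _run_sweep_phase(
    cfg: SimulationConfig,
    pops: list[_Population],
    attempt_rngs: list[np.random.Generator],
) -> tuple[list[_Population], SweepTruth]:
    """Evolve post-split/injection, conditioned on the sweep not being lost.

    All populations advance in lock-step; the run stops once the sweep
    population's derived frequency reaches ``sweep_target_freq`` AND at
    least ``split_generations`` generations have elapsed.  On loss, all
    populations rewind to the injection snapshot and a fresh rng child is
    used (restart cap ``max_restarts``).
    """
    site = int(cfg.sweep_site)  # type: ignore[arg-type]
    s = cfg.selection_coeff
    snapshots = [p.copy() for p in pops]
    keep = np.asarray([site], dtype=np.int64)
    uniform = np.ones(cfg.pop_size)
    max_gens = max(2000, 4 * cfg.split_generations)

    for attempt, rng in enumerate(attempt_rngs):
        cur = [p.copy() for p in snapshots]
        gen = 0
        lost = False
        while True:
            w = _sweep_weights(cur[cfg.sweep_pop], site, s)
            if w is None:
                lost = True
                break
            freq = cur[cfg.sweep_pop].freq_at(site)
            if freq >= cfg.sweep_target_freq and gen >= cfg.split_generations:
                truth = SweepTruth(position=site, final_freq=freq, generations=gen, restarts=attempt)
                return cur, truth
            if gen >= max_gens:
                lost = True  # stalled: treat as a failed attempt
                break
            for k, p in enumerate(cur):
                _advance(p, cfg, rng, w / w.sum() if k == cfg.sweep_pop else uniform)
                _prune_monomorphic(p, keep_positions=keep)
            gen += 1
        if not lost:  # pragma: no cover - loop exits via return
            break
    raise SimulationFailure(
        f"sweep at {site} lost in all {len(attempt_rngs)} attempts (s={s})"
    )


def simulate_sweep(config: SimulationConfig) -> tuple[HaplotypePanel, SweepTruth]:
    """Panel with a hard sweep at ``config.sweep_site``.

    The derived allele is injected on one haplotype of the (first, or
    ``sweep_pop``-th after a split) population right after burn-in and
    evolves with multiplicative fitness ``(1+s)`` per copy until its
    frequency reaches ``sweep_target_freq``; runs in which it is lost are
    restarted (cap ``max_restarts``).  With ``n_pops >= 2`` the burn-in pool
    is split first and the sweep runs in ``sweep_pop`` only, giving the
    pop1-vs-pop2 contrast the cross-population scan expects.

    With ``selection_coeff = 0`` no selection phase is run: the panel equals
    the neutral panel for the same seed plus the injected singleton.
    """
    if config.sweep_site is None:
        raise InvalidConfig("simulate_sweep requires sweep_site")
    ss = np.random.SeedSequence(config.seed)
    burn_seed, emit_seed, *attempt_seeds = ss.spawn(2 + config.max_restarts)
    pop = _burn_in(config, np.random.default_rng(burn_seed))

    site = int(config.sweep_site)
    j = np.searchsorted(pop.positions, site)
    if j < pop.positions.size and pop.positions[j] == site:
        # standing variant already at the site: restart its history as the
        # sweep allele by resetting it to a single copy
        pop.H[:, j] = 0
        pop.H[0, j] = 1
    else:
        col = np.zeros((pop.H.shape[0], 1), dtype=np.uint8)
        col[0, 0] = 1
        pop.H = np.insert(pop.H, j, col[:, 0], axis=1)
        pop.positions = np.insert(pop.positions, j, site)

    pops = [pop] + [pop.copy() for _ in range(config.n_pops - 1)]
    if config.sweep_pop != 0:
        pops[0], pops[config.sweep_pop] = pops[config.sweep_pop], pops[0]

    if config.selection_coeff == 0:
        truth = SweepTruth(site, 1.0 / pop.H.shape[0], 0, 0)
    else:
        rngs = [np.random.default_rng(s_) for s_ in attempt_seeds]
        pops, truth = _run_sweep_phase(config, pops, rngs)
    panel = _emit_panel(config, pops, np.random.default_rng(emit_seed))
    return panel, truth


def simulate_split_populations(config: SimulationConfig, return_ancestral: bool = False):
    """Split one burnt-in ancestral pool into isolated daughter populations.

    Each daughter evolves ``split_generations`` Wright-Fisher generations
    with no migration.  ``return_ancestral=True`` additionally returns a
    panel sampled from the pre-split pool (a stand-in for an unavailable
    wild reference; no downstream analysis requires it).
    """
    if config.n_pops < 2:
        raise InvalidConfig("simulate_split_populations requires n_pops >= 2")
    if config.selection_coeff != 0:
        raise InvalidConfig("use simulate_sweep for selected runs")
    ss = np.random.SeedSequence(config.seed)
    burn_seed, emit_seed, anc_seed, *pop_seeds = ss.spawn(3 + config.n_pops)
    ancestral = _burn_in(config, np.random.default_rng(burn_seed))

    uniform = np.ones(config.pop_size)
    pops = [ancestral.copy() for _ in range(config.n_pops)]
    for pop, seed in zip(pops, pop_seeds):
        rng = np.random.default_rng(seed)
        for _ in range(config.split_generations):
            _advance(pop, config, rng, uniform)
            _prune_monomorphic(pop)
    panel = _emit_panel(config, pops, np.random.default_rng(emit_seed))
    if return_ancestral:
        anc_cfg = _dc_replace(config, n_pops=1, split_generations=0)
        anc_panel = _emit_panel(anc_cfg, [ancestral], np.random.default_rng(anc_seed))
        return panel, anc_panel
    return panel


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as plain-text VCFv4.2 with phased GT columns.

    One record per site; REF/ALT are placeholder nucleotides A/T (the panel
    is binary); INFO carries ``AA=<ref>`` at sites whose ancestral allele is
    known, so polarity round-trips through the QC reader.
    """
    path = Path(path)
    n = panel.n_samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=selsweep\n")
        chroms = list(dict.fromkeys(panel.chrom_ids))
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length={panel.chrom_length(chrom)}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        H = panel.alleles
        for j in range(panel.n_sites):
            info = "AA=A" if panel.ancestral_known[j] else "."
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(n)
            )
            fh.write(
                f"{panel.chrom_ids[j]}\t{panel.positions[j]}\t.\tA\tT\t.\tPASS\t{info}\tGT\t{gts}\n"
            )
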