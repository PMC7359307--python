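"""Phased haplotype panels and population maps.

The :class:`HaplotypePanel` is the central in-memory container shared by the
simulator, the QC layer and the selection scans: a binary 2n x m allele
matrix (0 = ancestral/reference, 1 = derived/alternate) over m biallelic
SNPs, with strictly increasing physical positions per chromosome, sample
identifiers and a sample -> population map.  Haplotype rows come in
consecutive pairs, rows 2i and 2i+1 belonging to diploid sample i.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["HaplotypePanel", "concat_panels", "read_pop_map", "write_pop_map"]


@dataclass
class HaplotypePanel:
    """Phased, fully called binary SNP haplotypes for one or more populations.

    Parameters
    ----------
    alleles
        ``(2n, m)`` uint8 matrix; row ``2i``/``2i+1`` are the two phased
        haplotypes of sample ``i``.  0 codes the ancestral (or reference)
        allele, 1 the derived (or alternate) allele.
    positions
        ``(m,)`` 1-based physical coordinates, strictly increasing within
        each chromosome.
    chrom_ids
        ``(m,)`` chromosome label per site.
    sample_ids
        ``n`` sample identifiers, in row-pair order.
    population_of
        Mapping from sample id to population label.
    ancestral_known
        ``(m,)`` booleans; True where the 0/1 coding is genuinely
        ancestral/derived (always true for simulated panels, where the
        founder allele is ancestral by construction).
    chrom_lengths
        Optional chromosome length map (used to clamp windows and candidate
        regions); defaults to the last SNP position per chromosome.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom_ids: np.ndarray
    sample_ids: list[str]
    population_of: dict[str, str]
    ancestral_known: np.ndarray
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom_ids = np.asarray(self.chrom_ids, dtype=object)
        self.ancestral_known = np.asarray(self.ancestral_known, dtype=bool)
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance among samples."""
        seen: list[str] = []
        for s in self.sample_ids:
            p = self.population_of[s]
            if p not in seen:
                seen.append(p)
        return seen

    def validate(self) -> None:
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        n2, m = self.alleles.shape
        if n2 != 2 * len(self.sample_ids):
            raise ValueError(
                f"{n2} haplotype rows do not pair up with {len(self.sample_ids)} samples"
            )
        if self.positions.shape != (m,) or self.chrom_ids.shape != (m,):
            raise ValueError("positions/chrom_ids length must match allele columns")
        if self.ancestral_known.shape != (m,):
            raise ValueError("ancestral_known length must match allele columns")
        if m and (self.alleles > 1).any():
            raise ValueError("alleles must be strictly binary")
        for chrom in dict.fromkeys(self.chrom_ids):
            pos = self.positions[self.chrom_ids == chrom]
            if pos.size and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")
        missing = [s for s in self.sample_ids if s not in self.population_of]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")

    # -- derived views -----------------------------------------------------
    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix ``(n, m)`` with values 0/1/2 (no missing)."""
        return (self.alleles[0::2].astype(np.int8) + self.alleles[1::2]).astype(np.int8)

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency per site over all haplotypes."""
        return self.alleles.mean(axis=0)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.population_of[s] == population]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return np.asarray(idx, dtype=np.int64)

    def for_population(self, population: str) -> "HaplotypePanel":
        """Subset the panel to one population (all sites retained)."""
        idx = self.sample_indices(population)
        rows = np.empty(2 * idx.size, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        samples = [self.sample_ids[i] for i in idx]
        return replace(
            self,
            alleles=self.alleles[rows],
            sample_ids=samples,
            population_of={s: self.population_of[s] for s in samples},
        )

    def subset_sites(self, site_mask_or_index: np.ndarray) -> "HaplotypePanel":
        sel = np.asarray(site_mask_or_index)
        return replace(
            self,
            alleles=self.alleles[:, sel],
            positions=self.positions[sel],
            chrom_ids=self.chrom_ids[sel],
            ancestral_known=self.ancestral_known[sel],
        )

    def chrom_length(self, chrom: str) -> int:
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        pos = self.positions[self.chrom_ids == chrom]
        if pos.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(pos.max())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.population_of == other.population_of
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.chrom_ids, other.chrom_ids)
            and np.array_equal(self.ancestral_known, other.ancestral_known)
        )


def concat_panels(panels: list[HaplotypePanel]) -> HaplotypePanel:
    """Combine single-chromosome panels into one multi-chromosome panel.

    Each input must cover a distinct chromosome label set and describe the
    same sample structure (count and per-sample population labels, in
    order); the first panel's sample ids are kept.  This is how
    multi-chromosome panels are built from independent simulation runs.
    """
    if not panels:
        raise ValueError("need at least one panel")
    first = panels[0]
    chrom_sets: set[str] = set()
    for p in panels:
        if p.n_samples != first.n_samples:
            raise ValueError("panels describe different numbers of samples")
        pops_p = [p.population_of[s] for s in p.sample_ids]
        pops_f = [first.population_of[s] for s in first.sample_ids]
        if pops_p != pops_f:
            raise ValueError("panels describe different population structures")
        chroms = set(p.chrom_ids)
        if chroms & chrom_sets:
            raise ValueError(f"duplicate chromosome labels: {chroms & chrom_sets}")
        chrom_sets |= chroms
    lengths: dict[str, int] = {}
    for p in panels:
        for chrom in dict.fromkeys(p.chrom_ids):
            lengths[chrom] = p.chrom_length(chrom)
    return HaplotypePanel(
        alleles=np.hstack([p.alleles for p in panels]),
        positions=np.concatenate([p.positions for p in panels]),
        chrom_ids=np.concatenate([p.chrom_ids for p in panels]),
        sample_ids=list(first.sample_ids),
        population_of=dict(first.population_of),
        ancestral_known=np.concatenate([p.ancestral_known for p in panels]),
        chrom_lengths=lengths,
    )


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample->population TSV (no header)."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
        out[parts[0]] = parts[1]
    return out


def write_pop_map(population_of: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in population_of.items():
            fh.write(f"{sample}\t{pop}\n")
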