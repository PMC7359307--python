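"""Candidate SNPs, regions, genes and cross-method overlaps.

A scan SNP is a candidate when its -log10 p exceeds the Bonferroni-derived
threshold (7.4 for ~1.3 M tests at alpha 0.05); F_ST candidates are the top
0.5% of sliding windows (ties at the cutoff included).  Each candidate SNP
seeds an interval of 250 kb total width (+/-125 kb, clamped to the
chromosome); intervals from the same method and population are merged,
never across methods, so method-level overlaps are computed on gene sets.
Genes from a GFF3 annotation are attached on >= 1 bp closed-interval
overlap, and SNPs are classed exonic / intronic / intergenic by interval
logic alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneAnnotation",
    "CandidateRegion",
    "read_gff3",
    "bonferroni_threshold",
    "significant_snps",
    "top_fst_windows",
    "make_regions",
    "regions_from_windows",
    "intersect_genes",
    "method_overlap",
    "classify_effect",
    "regions_to_frame",
    "regions_to_bed",
]


@dataclass
class GeneAnnotation:
    """Gene and exon intervals (1-based inclusive, from GFF3)."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    exons: dict[str, list[tuple[int, int]]]  # gene_id -> [(start, end), ...]
    _gene_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _exon_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for row in self.genes.itertuples():
            if row.start > row.end:
                raise ValueError(f"gene {row.gene_id}: start > end")
            self._gene_trees.setdefault(row.chrom, IntervalTree()).addi(
                row.start, row.end + 1, row.gene_id
            )
        gene_chrom = dict(zip(self.genes["gene_id"], self.genes["chrom"]))
        for gid, ivs in self.exons.items():
            for s, e in ivs:
                self._exon_trees.setdefault(gene_chrom[gid], IntervalTree()).addi(
                    s, e + 1, gid
                )

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene ids overlapping [start, end] by >= 1 bp (sorted)."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})

    def chroms(self) -> set[str]:
        return set(self._gene_trees)


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Load gene and exon features from a GFF3 file.

    Exons are assigned to their ancestor gene through Parent links
    (gene -> mRNA -> exon or gene -> exon).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    exons: dict[str, list[tuple[int, int]]] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        rows.append(
            dict(
                gene_id=gid,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
            )
        )
        ivs = [
            (exon.start, exon.end)
            for exon in db.children(gene, featuretype="exon", order_by="start")
        ]
        exons[gid] = ivs
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(genes=genes, exons=exons)


@dataclass
class CandidateRegion:
    """Merged candidate interval from one scan method."""

    chrom: str
    start: int
    end: int
    method: str  # "iHS" | "Rsb" | "FST"
    population: str  # strain, or pair label for FST
    peak_pos: int
    peak_score: float
    genes: list[str] = field(default_factory=list)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n_tests): the genome-wide significance line."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(-math.log10(alpha / n_tests))


def significant_snps(scores: pd.DataFrame, threshold: float = 7.4) -> pd.DataFrame:
    """Rows whose -log10 p strictly exceeds the threshold."""
    if len(scores) == 0:
        return scores.copy()
    keep = scores["neg_log10_p"].to_numpy(dtype=float) > threshold
    return scores.loc[keep].reset_index(drop=True)


def top_fst_windows(windows: pd.DataFrame, fraction: float = 0.005) -> pd.DataFrame:
    """Highest-value ceil(fraction * n) windows; ties at the cutoff are all
    included.  Windows with undefined (NaN) values are excluded first."""
    defined = windows.loc[np.isfinite(windows["value"].to_numpy(dtype=float))]
    n = len(defined)
    if n == 0:
        return defined.reset_index(drop=True)
    k = max(1, math.ceil(fraction * n))
    order = defined.sort_values(
        ["value", "chrom", "start"], ascending=[False, True, True]
    )
    cutoff_value = order["value"].iloc[k - 1]
    return order.loc[order["value"] >= cutoff_value].reset_index(drop=True)


def make_regions(
    snps: pd.DataFrame,
    method: str,
    population: str,
    span: int = 250_000,
    chrom_lengths: dict[str, int] | None = None,
    score_col: str = "neg_log10_p",
) -> list[CandidateRegion]:
    """Candidate regions of total width ``span`` centred on each SNP.

    A SNP at position p yields [p - span/2 + 1, p + span/2], clamped to
    [1, chromosome length].  Overlapping intervals from this method and
    population are merged; the merged region's peak is its best-scoring
    SNP.
    """
    half = span // 2
    regions: list[CandidateRegion] = []
    snps = snps.sort_values(["chrom", "pos"])
    for chrom, grp in snps.groupby("chrom", sort=True):
        clen = (chrom_lengths or {}).get(chrom)
        cur: CandidateRegion | None = None
        for row in grp.itertuples():
            pos = int(row.pos)
            score = float(getattr(row, score_col))
            start = max(1, pos - half + 1)
            end = pos + half
            if clen is not None:
                end = min(end, clen)
            if cur is not None and start <= cur.end:
                cur.end = max(cur.end, end)
                if score > cur.peak_score:
                    cur.peak_score = score
                    cur.peak_pos = pos
            else:
                if cur is not None:
                    regions.append(cur)
                cur = CandidateRegion(
                    chrom=str(chrom), start=start, end=end, method=method,
                    population=population, peak_pos=pos, peak_score=score,
                )
        if cur is not None:
            regions.append(cur)
    return regions


def regions_from_windows(
    windows: pd.DataFrame, method: str, population: str
) -> list[CandidateRegion]:
    """Merge selected windows (e.g. top-F_ST) into candidate regions."""
    regions: list[CandidateRegion] = []
    windows = windows.sort_values(["chrom", "start"])
    for chrom, grp in windows.groupby("chrom", sort=True):
        cur: CandidateRegion | None = None
        for row in grp.itertuples():
            start, end, value = int(row.start), int(row.end), float(row.value)
            mid = (start + end) // 2
            if cur is not None and start <= cur.end:
                cur.end = max(cur.end, end)
                if value > cur.peak_score:
                    cur.peak_score = value
                    cur.peak_pos = mid
            else:
                if cur is not None:
                    regions.append(cur)
                cur = CandidateRegion(
                    chrom=str(chrom), start=start, end=end, method=method,
                    population=population, peak_pos=mid, peak_score=value,
                )
        if cur is not None:
            regions.append(cur)
    return regions


def intersect_genes(
    regions: list[CandidateRegion], annotation: GeneAnnotation
) -> list[CandidateRegion]:
    """Attach overlapping gene ids to each region (>= 1 bp closed-interval
    overlap; adjacency is not overlap).  Regions on contigs absent from the
    annotation get an empty list, with a warning."""
    known = annotation.chroms()
    missing: set[str] = set()
    for region in regions:
        if region.chrom not in known:
            missing.add(region.chrom)
            region.genes = []
            continue
        region.genes = annotation.genes_overlapping(
            region.chrom, region.start, region.end
        )
    if missing:
        warnings.warn(
            f"contigs absent from annotation: {sorted(missing)}", stacklevel=2
        )
    return regions


def method_overlap(gene_sets: dict[str, set[str]]) -> dict[str, int]:
    """All 7 Venn cells for three method-level gene sets.

    Keys of ``gene_sets`` are method names (e.g. iHS, Rsb, FST).  Returns
    exclusive cell counts keyed like "iHS", "iHS&Rsb", "iHS&Rsb&FST".
    """
    names = list(gene_sets)
    if len(names) != 3:
        raise ValueError("method_overlap expects exactly three gene sets")
    a, b, c = (gene_sets[n] for n in names)
    cells = {
        names[0]: a - b - c,
        names[1]: b - a - c,
        names[2]: c - a - b,
        f"{names[0]}&{names[1]}": (a & b) - c,
        f"{names[0]}&{names[2]}": (a & c) - b,
        f"{names[1]}&{names[2]}": (b & c) - a,
        f"{names[0]}&{names[1]}&{names[2]}": a & b & c,
    }
    return {k: len(v) for k, v in cells.items()}


def classify_effect(chrom: str, pos: int, annotation: GeneAnnotation) -> str:
    """"exonic" if inside any exon, else "intronic" if inside a gene, else
    "intergenic" (strand and UTR subtypes ignored)."""
    etree = annotation._exon_trees.get(chrom)
    if etree is not None and etree.overlap(pos, pos + 1):
        return "exonic"
    gtree = annotation._gene_trees.get(chrom)
    if gtree is not None and gtree.overlap(pos, pos + 1):
        return "intronic"
    return "intergenic"


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=r.chrom, start=r.start, end=r.end, method=r.method,
                population=r.population, peak_pos=r.peak_pos,
                peak_score=r.peak_score, genes=",".join(r.genes),
            )
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "method", "population",
            "peak_pos", "peak_score", "genes",
        ],
    )


def regions_to_bed(regions: list[CandidateRegion], path: str | Path) -> None:
    """BED (0-based half-open) export of candidate regions."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.method}:{r.population}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.peak_score:.4g}\n")
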