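"""Variant- and sample-level quality control.

Implements the conventional resequencing QC chain for multi-strain SNP
panels: sequential site filters (indels, multi-allelics, low QUAL, low call
rate, mitochondrial contigs, Hardy-Weinberg disequilibrium, low MAF — the
last two evaluated per population, a site surviving only if it passes in
every population), an 80% sample call-rate filter, and relatedness pruning
from method-of-moments identity-by-descent estimates (PLINK-style PI_HAT).

All thresholds are strict inequalities: a value exactly at a threshold
passes.  The Hardy-Weinberg test is the exact conditional test on genotype
counts (Wigginton et al. 2005).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import HaplotypePanel

__all__ = [
    "VariantDataset",
    "QCReport",
    "PairwiseIBD",
    "DEFAULT_THRESHOLDS",
    "read_vcf",
    "filter_variants",
    "hwe_exact_test",
    "filter_samples_by_call_rate",
    "estimate_ibd",
    "prune_related",
    "apply_qc",
]

MISSING = -1

#: QC thresholds for resequencing panels: QUAL phred < 30, site call rate
#: < 0.90, HWE exact p < 1e-9 and MAF < 0.05 (per population), sample call
#: rate below 0.80, PI_HAT > 0.5.  Boundary values pass (strict inequalities).
DEFAULT_THRESHOLDS: dict[str, object] = {
    "min_qual": 30.0,
    "min_site_call_rate": 0.90,
    "mito_contigs": ("MT",),
    "hwe_min_p": 1e-9,
    "min_maf": 0.05,
    "min_sample_call_rate": 0.80,
    "max_pi_hat": 0.5,
}


@dataclass
class VariantDataset:
    """Genotypes plus per-site metadata as read from a VCF.

    ``genotypes`` is an ``(n_samples, n_sites)`` int8 dosage matrix
    (0/1/2, ``MISSING`` = -1).  ``haplotypes`` is the phased ``(2n, m)``
    binary matrix when every genotype in the file was phased and called,
    else None.  ``variants`` is a DataFrame with columns chrom, pos, ref,
    alt, qual, call_rate, is_indel, n_alleles, ancestral_known.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]
    population_of: dict[str, str]
    haplotypes: np.ndarray | None = None
    chrom_lengths: dict[str, int] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def to_panel(self) -> HaplotypePanel:
        """Phased-haplotype view; raises if any genotype is unphased/missing."""
        if self.haplotypes is None:
            raise ValueError(
                "dataset is not fully phased and called; haplotype scans "
                "require phased, complete genotypes (phase upstream)"
            )
        return HaplotypePanel(
            alleles=self.haplotypes,
            positions=self.variants["pos"].to_numpy(),
            chrom_ids=self.variants["chrom"].to_numpy(dtype=object),
            sample_ids=list(self.sample_ids),
            population_of=dict(self.population_of),
            ancestral_known=self.variants["ancestral_known"].to_numpy(dtype=bool),
            chrom_lengths=self.chrom_lengths,
        )

    def subset(self, site_idx: np.ndarray | None = None, sample_idx: np.ndarray | None = None) -> "VariantDataset":
        g = self.genotypes
        h = self.haplotypes
        var = self.variants
        samples = self.sample_ids
        if site_idx is not None:
            g = g[:, site_idx]
            var = var.iloc[np.asarray(site_idx)].reset_index(drop=True)
            if h is not None:
                h = h[:, site_idx]
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx]
            samples = [self.sample_ids[i] for i in sample_idx]
            if h is not None:
                rows = np.empty(2 * sample_idx.size, dtype=np.int64)
                rows[0::2] = 2 * sample_idx
                rows[1::2] = 2 * sample_idx + 1
                h = h[rows]
        return VariantDataset(
            genotypes=np.ascontiguousarray(g),
            variants=var,
            sample_ids=samples,
            population_of={s: self.population_of[s] for s in samples},
            haplotypes=None if h is None else np.ascontiguousarray(h),
            chrom_lengths=self.chrom_lengths,
        )

    def pop_indices(self) -> dict[str, np.ndarray]:
        pops: dict[str, list[int]] = {}
        for i, s in enumerate(self.sample_ids):
            pops.setdefault(self.population_of[s], []).append(i)
        return {p: np.asarray(ix, dtype=np.int64) for p, ix in pops.items()}


@dataclass
class QCReport:
    """Ordered audit of removals; counts reconcile with input/output sizes."""

    steps: list[tuple[str, int, str]] = field(default_factory=list)
    n_input: int = 0
    n_output: int = 0

    def add(self, name: str, n_removed: int, threshold: str) -> None:
        self.steps.append((name, int(n_removed), threshold))

    def total_removed(self) -> int:
        return sum(n for _, n, _ in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_removed", "threshold"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PairwiseIBD:
    """Method-of-moments IBD sharing for one sample pair."""

    sample_a: str
    sample_b: str
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_informative: int
    unstable: bool  # fewer than 50 informative SNPs


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, pop_map: dict[str, str] | str | Path) -> VariantDataset:
    """Read a VCF into dosages (and haplotypes when fully phased).

    ``pop_map`` maps sample id -> population (or is a path to a two-column
    TSV).  Samples present in the VCF but absent from the map raise a
    configuration error.  The INFO/AA key, when present, marks the site's
    ancestral allele; sites where AA equals neither REF nor ALT are treated
    as polarity-unknown.
    """
    from cyvcf2 import VCF

    from .panel import read_pop_map

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pop_map]
    if missing_samples:
        raise ValueError(
            f"samples missing from population map: {missing_samples[:5]}"
        )

    rows = []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    n = len(samples)
    for v in vcf:
        gts = v.genotype.array()  # (n, 3): allele0, allele1, phased flag
        a0 = gts[:, 0].astype(np.int16)
        a1 = gts[:, 1].astype(np.int16)
        called = (a0 >= 0) & (a1 >= 0)
        dose = np.where(called, (a0 > 0).astype(np.int8) + (a1 > 0), MISSING).astype(np.int8)
        geno_cols.append(dose)
        phased_here = bool(called.all() and gts[:, 2].all())
        if phased_here:
            hap = np.empty(2 * n, dtype=np.uint8)
            hap[0::2] = (a0 > 0).astype(np.uint8)
            hap[1::2] = (a1 > 0).astype(np.uint8)
            hap_cols.append(hap)
        else:
            all_phased = False

        alt = v.ALT[0] if v.ALT else ""
        aa = v.INFO.get("AA")
        anc_known = aa is not None and aa in (v.REF, alt)
        if aa is not None and aa == alt:
            # derived coding flipped relative to REF/ALT: flip here so that
            # 0 is always ancestral downstream
            dose_f = np.where(dose == MISSING, MISSING, 2 - dose).astype(np.int8)
            geno_cols[-1] = dose_f
            if phased_here:
                hap_cols[-1] = (1 - hap_cols[-1]).astype(np.uint8)
        rows.append(
            dict(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                qual=np.nan if v.QUAL is None else float(v.QUAL),
                call_rate=float(called.mean()) if n else 0.0,
                is_indel=bool(v.is_indel),
                n_alleles=1 + len(v.ALT),
                ancestral_known=anc_known,
            )
        )
    chrom_lengths = None
    try:
        if vcf.seqnames:
            chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header without contig length lines
        chrom_lengths = None

    variants = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "qual", "call_rate",
            "is_indel", "n_alleles", "ancestral_known",
        ],
    )
    genotypes = (
        np.stack(geno_cols, axis=1) if geno_cols else np.empty((n, 0), dtype=np.int8)
    )
    haplotypes = None
    if all_phased:
        haplotypes = (
            np.stack(hap_cols, axis=1) if hap_cols else np.empty((2 * n, 0), dtype=np.uint8)
        )
    return VariantDataset(
        genotypes=genotypes,
        variants=variants,
        sample_ids=samples,
        population_of={s: pop_map[s] for s in samples},
        haplotypes=haplotypes,
        chrom_lengths=chrom_lengths,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as the minor-allele count) whose
    null probability does not exceed the observed one.  Monomorphic sites
    return p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-or-major allele count; symmetric below
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    hets = np.arange(rare % 2, rare + 1, 2)
    # P(n_Aa = h | n, rare) ∝ n! / (nAA! nAa! naa!) * 2^h, with fixed allele counts
    n_aa_all = (rare - hets) // 2  # homozygotes of the rarer allele
    n_AA_all = n - hets - n_aa_all  # homozygotes of the commoner allele
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_aa_all + 1)
        - gammaln(n_AA_all + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


def _hwe_pvalues(counts: np.ndarray) -> np.ndarray:
    """Vectorised wrapper: counts is (m, 3) of (n_AA, n_Aa, n_aa)."""
    return np.asarray([hwe_exact_test(*map(int, c)) for c in counts])


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

def _genotype_counts(genotypes: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """(m, 3) counts of (hom-ref, het, hom-alt) among called genotypes."""
    g = genotypes[idx]
    return np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)], axis=1)


def _maf_from_counts(counts: np.ndarray) -> np.ndarray:
    n_called = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * counts[:, 2] + counts[:, 1]) / (2 * n_called)
    maf = np.minimum(p, 1 - p)
    return np.where(n_called > 0, maf, 0.0)


def filter_variants(
    dataset: VariantDataset,
    thresholds: dict[str, object] | None = None,
) -> tuple[np.ndarray, QCReport]:
    """Apply the seven sequential site filters; returns (kept index, report).

    Order: (1) indels, (2) >2 alleles, (3) QUAL < 30, (4) call rate < 0.90,
    (5) mitochondrial contig, (6) HWE exact p < 1e-9 in any population,
    (7) MAF < 0.05 in any population.  Missing QUAL passes filter 3.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    var = dataset.variants
    m = len(var)
    report = QCReport(n_input=m)
    alive = np.ones(m, dtype=bool)

    def drop(name: str, bad: np.ndarray, desc: str) -> None:
        bad = bad & alive
        report.add(name, bad.sum(), desc)
        alive[bad] = False

    drop("indel", var["is_indel"].to_numpy(dtype=bool), "is_indel")
    drop("multiallelic", var["n_alleles"].to_numpy() > 2, "n_alleles > 2")
    qual = var["qual"].to_numpy(dtype=float)
    drop("qual", ~np.isnan(qual) & (qual < th["min_qual"]), f"QUAL < {th['min_qual']}")
    drop(
        "site_call_rate",
        var["call_rate"].to_numpy(dtype=float) < th["min_site_call_rate"],
        f"call rate < {th['min_site_call_rate']}",
    )
    drop(
        "mitochondrial",
        var["chrom"].isin(list(th["mito_contigs"])).to_numpy(),
        f"chrom in {tuple(th['mito_contigs'])}",
    )

    pop_idx = dataset.pop_indices()
    # HWE and MAF are evaluated within each population; a site survives only
    # if it passes in every population (kept set = intersection).
    hwe_bad = np.zeros(m, dtype=bool)
    cand = np.flatnonzero(alive)
    counts_by_pop = {}
    for pop, idx in pop_idx.items():
        counts = _genotype_counts(dataset.genotypes[:, cand], idx)
        counts_by_pop[pop] = counts
        pvals = _hwe_pvalues(counts)
        hwe_bad[cand[pvals < th["hwe_min_p"]]] = True
    drop("hwe", hwe_bad, f"exact p < {th['hwe_min_p']} in any population")

    maf_bad = np.zeros(m, dtype=bool)
    still = alive[cand]
    for pop, counts in counts_by_pop.items():
        maf = _maf_from_counts(counts)
        maf_bad[cand[still & (maf < th["min_maf"])]] = True
    drop("maf", maf_bad, f"MAF < {th['min_maf']} in any population")

    kept = np.flatnonzero(alive)
    report.n_output = kept.size
    assert report.n_input - report.total_removed() == report.n_output
    return kept, report


def filter_samples_by_call_rate(
    genotypes: np.ndarray, min_rate: float = 0.80
) -> np.ndarray:
    """Indices of samples whose genotype call rate is >= ``min_rate``."""
    if genotypes.shape[1] == 0:
        return np.arange(genotypes.shape[0])
    rate = (genotypes != MISSING).mean(axis=1)
    return np.flatnonzero(rate >= min_rate)


# ---------------------------------------------------------------------------
# IBD / relatedness
# ---------------------------------------------------------------------------

def estimate_ibd(
    genotypes: np.ndarray,
    sample_ids: list[str] | None = None,
    allele_freqs: np.ndarray | None = None,
    min_informative: int = 50,
) -> list[PairwiseIBD]:
    """Method-of-moments P(IBD=0/1/2) and PI_HAT for every sample pair.

    Follows the PLINK --genome construction: observed identity-by-state
    counts per pair are compared with their expectations given pooled
    allele frequencies; the resulting probabilities are clamped to [0, 1]
    and renormalised, and PI_HAT = P(IBD=2) + P(IBD=1)/2.  Pairs with fewer
    than ``min_informative`` informative SNPs are flagged unstable.
    """
    n, m = genotypes.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    called = genotypes != MISSING
    if allele_freqs is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            allele_freqs = np.where(
                called.any(axis=0),
                np.where(called, genotypes, 0).sum(axis=0) / (2 * called.sum(axis=0)),
                np.nan,
            )
    p = np.asarray(allele_freqs, dtype=float)
    q = 1 - p
    poly = np.isfinite(p) & (p > 0) & (p < 1)

    # per-site P(IBS=i | IBD=j) pieces (no small-sample correction)
    e_ibs0_ibd0 = np.where(poly, 2 * p**2 * q**2, 0.0)
    e_ibs1_ibd0 = np.where(poly, 4 * p**3 * q + 4 * p * q**3, 0.0)
    e_ibs1_ibd1 = np.where(poly, 2 * p**2 * q + 2 * p * q**2, 0.0)

    out: list[PairwiseIBD] = []
    g = genotypes.astype(np.int16)
    for i in range(n - 1):
        for j in range(i + 1, n):
            use = called[i] & called[j] & poly
            ni = int(use.sum())
            if ni == 0:
                out.append(PairwiseIBD(sample_ids[i], sample_ids[j], np.nan, np.nan, np.nan, np.nan, 0, True))
                continue
            diff = np.abs(g[i] - g[j])[use]
            s0 = float((diff == 2).sum())
            s1 = float((diff == 1).sum())
            s2 = float((diff == 0).sum())
            e00 = e_ibs0_ibd0[use].sum()
            e10 = e_ibs1_ibd0[use].sum()
            e11 = e_ibs1_ibd1[use].sum()
            # sequential method-of-moments solve: IBS0 only arises under
            # IBD=0; IBS1 under IBD<=1; IBS2 under any IBD state
            e20 = ni - e00 - e10  # E[#IBS2 | IBD=0]
            e21 = ni - e11  # E[#IBS2 | IBD=1]
            z0 = s0 / e00 if e00 > 0 else 0.0
            z1 = (s1 - z0 * e10) / e11 if e11 > 0 else 0.0
            z2 = (s2 - z0 * e20 - z1 * e21) / ni
            z = np.clip([z0, z1, z2], 0.0, 1.0)
            tot = z.sum()
            if tot > 0:
                z = z / tot
            pi_hat = float(np.clip(z[2] + 0.5 * z[1], 0.0, 1.0))
            out.append(
                PairwiseIBD(
                    sample_ids[i], sample_ids[j],
                    float(z[0]), float(z[1]), float(z[2]),
                    pi_hat, ni, ni < min_informative,
                )
            )
    return out


def prune_related(
    ibd_list: list[PairwiseIBD],
    call_rates: dict[str, float] | None = None,
    threshold: float = 0.5,
) -> list[str]:
    """Greedy pruning of related pairs (PI_HAT > threshold).

    Repeatedly takes the highest-PI_HAT offending pair and removes the
    member with the lower call rate (tie: the lexicographically later
    sample id).  Returns removed sample ids in removal order.
    """
    call_rates = call_rates or {}
    pairs = [p for p in ibd_list if np.isfinite(p.pi_hat)]
    removed: list[str] = []
    active = sorted(pairs, key=lambda p: (-p.pi_hat, p.sample_a, p.sample_b))
    gone: set[str] = set()
    while True:
        nxt = next(
            (p for p in active
             if p.pi_hat > threshold and p.sample_a not in gone and p.sample_b not in gone),
            None,
        )
        if nxt is None:
            break
        ca = call_rates.get(nxt.sample_a, 1.0)
        cb = call_rates.get(nxt.sample_b, 1.0)
        if ca < cb:
            victim = nxt.sample_a
        elif cb < ca:
            victim = nxt.sample_b
        else:
            victim = max(nxt.sample_a, nxt.sample_b)
        gone.add(victim)
        removed.append(victim)
    return removed


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def apply_qc(
    dataset: VariantDataset,
    thresholds: dict[str, object] | None = None,
) -> tuple[VariantDataset, QCReport, QCReport]:
    """Full QC: site filters, then sample call rate, then IBD pruning.

    Returns the filtered dataset plus a variant-level and a sample-level
    report.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    kept_sites, var_report = filter_variants(dataset, th)
    ds = dataset.subset(site_idx=kept_sites)

    sample_report = QCReport(n_input=ds.n_samples, n_output=ds.n_samples)
    if ds.n_sites == 0:  # nothing informative left for sample-level QC
        return ds, var_report, sample_report
    kept_samples = filter_samples_by_call_rate(ds.genotypes, th["min_sample_call_rate"])
    sample_report.add(
        "sample_call_rate",
        ds.n_samples - kept_samples.size,
        f"call rate < {th['min_sample_call_rate']}",
    )
    ds = ds.subset(sample_idx=kept_samples)

    ibd = estimate_ibd(ds.genotypes, ds.sample_ids)
    rates = dict(zip(ds.sample_ids, (ds.genotypes != MISSING).mean(axis=1)))
    to_remove = prune_related(ibd, rates, th["max_pi_hat"])
    sample_report.add("ibd", len(to_remove), f"PI_HAT > {th['max_pi_hat']}")
    if to_remove:
        keep = np.asarray(
            [i for i, s in enumerate(ds.sample_ids) if s not in set(to_remove)]
        )
        ds = ds.subset(sample_idx=keep)
    sample_report.n_output = ds.n_samples
    return ds, var_report, sample_report
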