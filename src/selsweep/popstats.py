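"""Diversity, linkage disequilibrium, differentiation and structure.

Per-population observed/expected heterozygosity, windowed nucleotide
diversity (pi), binned r^2 decay, per-SNP and sliding-window Weir &
Cockerham (1984) F_ST, and PCA of the scaled genotype matrix.

Window conventions: 1-based inclusive coordinates, windows anchored at
position 1 and advanced by the step, truncated at the chromosome end.
Window F_ST uses the weighted (ratio-of-sums) estimator
``sum(a) / sum(a + b + c)``; negative per-SNP components are retained so
window sums stay unbiased.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qc import MISSING

__all__ = [
    "heterozygosity",
    "site_pi",
    "nucleotide_diversity_windows",
    "ld_r2_decay",
    "wc_fst_components",
    "wc_fst_per_snp",
    "wc_fst_windows",
    "mean_weighted_fst",
    "pca",
]


# ---------------------------------------------------------------------------
# Heterozygosity and pi
# ---------------------------------------------------------------------------

def heterozygosity(genotypes: np.ndarray) -> tuple[float, float]:
    """Mean observed and expected heterozygosity over sites.

    Per site, Ho is the heterozygote fraction among called genotypes and
    He = 2 p (1 - p) from the called allele frequency (no small-sample
    correction).  Sites with no called genotypes are skipped.
    """
    called = genotypes != MISSING
    n_called = called.sum(axis=0)
    ok = n_called > 0
    if not ok.any():
        return float("nan"), float("nan")
    g = np.where(called, genotypes, 0)
    ho = (genotypes == 1).sum(axis=0)[ok] / n_called[ok]
    p = g.sum(axis=0)[ok] / (2 * n_called[ok])
    he = 2 * p * (1 - p)
    return float(ho.mean()), float(he.mean())


def site_pi(genotypes: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2 j (k - j) / (k (k - 1)).

    ``j`` = alternate allele count, ``k`` = called allele count: the mean
    pairwise difference among the k sampled alleles at the site.
    """
    called = genotypes != MISSING
    k = 2 * called.sum(axis=0)
    j = np.where(called, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (k - j) / (k * (k - 1.0))
    return np.where(k >= 2, pi, 0.0)


def _window_starts(chrom_len: int, window: int, step: int) -> np.ndarray:
    if window < step:
        raise ValueError("window must be >= step")
    return np.arange(1, chrom_len + 1, step, dtype=np.int64)


def nucleotide_diversity_windows(
    genotypes: np.ndarray,
    positions: np.ndarray,
    chrom_ids: np.ndarray,
    chrom_lengths: dict[str, int] | None = None,
    window: int = 250_000,
    step: int = 10_000,
) -> pd.DataFrame:
    """Sliding-window pi: sum of per-site pi over SNPs in the window divided
    by the window length in base pairs.

    Returns a DataFrame with columns chrom, start, end, n_snps, value.
    """
    pis = site_pi(genotypes)
    rows = []
    chrom_ids = np.asarray(chrom_ids, dtype=object)
    for chrom in dict.fromkeys(chrom_ids):
        in_chrom = chrom_ids == chrom
        pos = positions[in_chrom]
        pi_c = pis[in_chrom]
        clen = (chrom_lengths or {}).get(chrom, int(pos.max()) if pos.size else 0)
        for start in _window_starts(clen, window, step):
            end = min(start + window - 1, clen)
            lo, hi = np.searchsorted(pos, [start, end + 1])
            rows.append(
                dict(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    n_snps=int(hi - lo),
                    value=float(pi_c[lo:hi].sum() / (end - start + 1)),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_r2_decay(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    max_dist: int = 1_000_000,
    bin_width: int = 100_000,
) -> pd.DataFrame:
    """Mean r^2 between SNP pairs grouped into physical-distance bins.

    r^2 is the squared Pearson correlation of the binary allele indicator
    columns (equivalently D^2 / (pA qA pB qB) on haplotype frequencies).
    Pairs involving a monomorphic site are skipped.  Bins are contiguous
    [lo, hi) intervals of ``bin_width`` starting at 0.

    Returns a DataFrame with columns bin_lo, bin_hi, mean_r2, n_pairs.
    """
    H = np.asarray(haplotypes, dtype=np.float64)
    n, m = H.shape
    pos = np.asarray(positions, dtype=np.int64)
    sums = H.sum(axis=0)
    poly = (sums > 0) & (sums < n)

    n_bins = int(np.ceil(max_dist / bin_width)) if max_dist > 0 else 0
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=np.int64)

    mean = sums / n
    sd = H.std(axis=0)
    # pair sites by column offset so each offset is one vectorised pass
    for d in range(1, m):
        dist = pos[d:] - pos[:-d]
        use = (dist <= max_dist) & poly[d:] & poly[:-d]
        if not use.any():
            if (dist > max_dist).all():
                break
            continue
        i = np.flatnonzero(use)
        j = i + d
        cov = (H[:, i] * H[:, j]).mean(axis=0) - mean[i] * mean[j]
        r2 = (cov / (sd[i] * sd[j])) ** 2
        b = (dist[i] // bin_width).astype(np.int64)
        b = np.minimum(b, n_bins - 1)
        np.add.at(acc, b, r2)
        np.add.at(cnt, b, 1)

    lo = np.arange(n_bins, dtype=np.int64) * bin_width
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(
        dict(bin_lo=lo, bin_hi=lo + bin_width, mean_r2=mean_r2, n_pairs=cnt)
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_fst_components(
    genotypes_by_pop: list[np.ndarray],
) -> pd.DataFrame:
    """Per-SNP Weir & Cockerham (1984) variance components a, b, c.

    Vectorised over sites for ``r`` populations (the pairwise case used in
    strain comparisons has r = 2).  ``theta`` = a / (a + b + c); NaN where
    the site is monomorphic across all populations (denominator 0).

    Returns a DataFrame with columns a, b, c, theta.
    """
    r = len(genotypes_by_pop)
    if r < 2:
        raise ValueError("need at least two populations")
    m = genotypes_by_pop[0].shape[1]
    n_i = np.empty((r, m))
    p_i = np.empty((r, m))
    h_i = np.empty((r, m))
    for k, g in enumerate(genotypes_by_pop):
        called = g != MISSING
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(called, g, 0).sum(axis=0) / (2 * n_i[k])
        h_i[k] = (g == 1).sum(axis=0) / np.maximum(n_i[k], 1)

    n_bar = n_i.mean(axis=0)
    n_tot = r * n_bar
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_tot

        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = n_bar / n_c * (s2 - (inner - h_bar / 4) / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        denom = a + b + c
        # monomorphic across all populations -> all components 0 -> NaN flag
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    return pd.DataFrame(dict(a=a, b=b, c=c, theta=theta))


def wc_fst_per_snp(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> pd.DataFrame:
    """Two-population per-SNP Weir-Cockerham components (see
    :func:`wc_fst_components`)."""
    return wc_fst_components([genotypes_a, genotypes_b])


def wc_fst_windows(
    components: pd.DataFrame,
    positions: np.ndarray,
    chrom_ids: np.ndarray,
    chrom_lengths: dict[str, int] | None = None,
    window: int = 250_000,
    step: int = 25_000,
) -> pd.DataFrame:
    """Sliding-window weighted F_ST: sum(a) / sum(a+b+c) over window SNPs.

    Windows without polymorphic SNPs get value NaN (excluded from ranking).
    Returns a DataFrame with columns chrom, start, end, n_snps, value.
    """
    a = components["a"].to_numpy(dtype=float)
    abc = a + components["b"].to_numpy(dtype=float) + components["c"].to_numpy(dtype=float)
    usable = np.isfinite(components["theta"].to_numpy(dtype=float))
    rows = []
    chrom_ids = np.asarray(chrom_ids, dtype=object)
    for chrom in dict.fromkeys(chrom_ids):
        in_chrom = chrom_ids == chrom
        pos = positions[in_chrom]
        a_c, abc_c, use_c = a[in_chrom], abc[in_chrom], usable[in_chrom]
        clen = (chrom_lengths or {}).get(chrom, int(pos.max()) if pos.size else 0)
        for start in _window_starts(clen, window, step):
            end = min(start + window - 1, clen)
            lo, hi = np.searchsorted(pos, [start, end + 1])
            use = use_c[lo:hi]
            n_snps = int(use.sum())
            denom = abc_c[lo:hi][use].sum()
            value = float(a_c[lo:hi][use].sum() / denom) if n_snps and denom != 0 else float("nan")
            rows.append(dict(chrom=chrom, start=int(start), end=int(end), n_snps=n_snps, value=value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "value"])


def mean_weighted_fst(components: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums Weir-Cockerham F_ST."""
    ok = np.isfinite(components["theta"].to_numpy(dtype=float))
    a = components.loc[ok, "a"].to_numpy(dtype=float)
    abc = a + components.loc[ok, "b"].to_numpy(dtype=float) + components.loc[ok, "c"].to_numpy(dtype=float)
    return float(a.sum() / abc.sum())


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(genotypes: np.ndarray, n_components: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the scaled genotype matrix.

    Missing genotypes are mean-imputed per site (for this operation only);
    each site is centred at 2 p and scaled by sqrt(p (1 - p)).  Returns
    (eigenvalues, coordinates, pct_variance): eigenvalues of the sample
    covariance sorted descending, per-sample coordinates on the top
    components, and the percentage of total variance each explains.
    """
    n, m = genotypes.shape
    if n < 2:
        raise ValueError("need at least two samples")
    g = genotypes.astype(np.float64)
    called = genotypes != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / (2 * called.sum(axis=0))
    g = np.where(called, g, 2 * p)
    scale = np.sqrt(p * (1 - p))
    keep = np.isfinite(p) & (scale > 0)
    x = (g[:, keep] - 2 * p[keep]) / scale[keep]

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (n - 1)
    k = min(n_components, s.size)
    coords = u[:, :k] * s[:k]
    pct = 100.0 * eigvals / eigvals.sum()
    return eigvals[:k], coords, pct[:k]
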