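"""Extended-haplotype-homozygosity statistics: EHH, iHH, iHS, EHHS/iES, Rsb.

EHH for a core allele at distance s is the probability that two randomly
chosen carrier chromosomes are identical over the whole interval from the
core out to s:

    EHH(s) = sum_h C(n_h, 2) / C(n_c, 2)

with n_c carriers of the core allele and n_h the size of each distinct
haplotype class over [core, s].  iHH integrates the curve over physical
distance (trapezoid, both directions), truncated where EHH first drops
below a cutoff (default 0.05, interpolated crossing included); curves that
hit the chromosome edge above the cutoff are edge-censored and excluded
from standardization.

iHS is ln(iHH_ancestral / iHH_derived), standardized to zero mean and unit
variance within derived-allele-frequency bins, so that extreme values flag
unusually long haplotypes around one allele irrespective of its frequency.
EHHS pools both alleles (haplotype homozygosity across all chromosomes,
normalized to 1 at the core); its integral iES, compared between two
populations as Rsb = ln(iES_pop1 / iES_pop2) and standardized genome-wide,
needs no ancestral/derived polarity.  Positive Rsb marks longer haplotypes
(candidate selection) in pop1, negative in pop2.

Scores are approximately standard normal, so two-sided p-values are
reported as -log10(2 * (1 - Phi(|score|))).

Distances are physical base pairs (the panels carry no genetic map).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

from .panel import HaplotypePanel

__all__ = [
    "EHHCurve",
    "StandardizationBins",
    "DEFAULT_CUTOFF",
    "ehh",
    "ihh",
    "ihs",
    "ies",
    "rsb",
    "scan_pvalues",
]

#: EHH level below which integration stops (standard scan default).
DEFAULT_CUTOFF = 0.05

_POOLED = -1  # core_allele code for EHHS curves


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _refine_step(H, rows, j, group, ng, keymap, tkeys, counts):
    """Split haplotype classes by the allele at column j; returns
    (new group count, sum over classes of c*(c-1))."""
    n = rows.size
    ng_new = 0
    nt = 0
    for t in range(n):
        key = group[t] * 2 + H[rows[t], j]
        g = keymap[key]
        if g < 0:
            g = ng_new
            keymap[key] = g
            tkeys[nt] = key
            nt += 1
            ng_new += 1
        group[t] = g
    for k in range(nt):
        keymap[tkeys[k]] = -1
    for g in range(ng_new):
        counts[g] = 0
    for t in range(n):
        counts[group[t]] += 1
    s = 0
    for g in range(ng_new):
        s += counts[g] * (counts[g] - 1)
    return ng_new, s


@njit(cache=True)
def _curve_side(H, rows, core, direction, positions, ehh_out, pos_out):
    """Full EHH curve on one side, until EHH reaches 0 or the chromosome
    edge.  Fills outputs outward from the core; returns number of points."""
    n = rows.size
    m = H.shape[1]
    group = np.zeros(n, np.int64)
    keymap = np.full(2 * n + 2, -1, np.int64)
    tkeys = np.empty(2 * n + 2, np.int64)
    counts = np.zeros(n + 1, np.int64)
    ng = 1
    denom = n * (n - 1)
    k = 0
    j = core
    while True:
        j += direction
        if j < 0 or j >= m:
            return k
        ng, s = _refine_step(H, rows, j, group, ng, keymap, tkeys, counts)
        ehh_out[k] = s / denom
        pos_out[k] = positions[j]
        k += 1
        if s == 0:
            return k


@njit(cache=True)
def _ihh_side(H, rows, core, direction, cutoff, positions):
    """Fused EHH decay + trapezoid integration on one side.

    Returns (area in bp, complete flag); complete is False when the
    chromosome edge is reached while EHH is still above the cutoff.
    """
    n = rows.size
    m = H.shape[1]
    group = np.zeros(n, np.int64)
    keymap = np.full(2 * n + 2, -1, np.int64)
    tkeys = np.empty(2 * n + 2, np.int64)
    counts = np.zeros(n + 1, np.int64)
    ng = 1
    denom = n * (n - 1)
    area = 0.0
    prev_ehh = 1.0
    prev_pos = positions[core]
    j = core
    while True:
        j += direction
        if j < 0 or j >= m:
            return area, False
        ng, s = _refine_step(H, rows, j, group, ng, keymap, tkeys, counts)
        ehh = s / denom
        d = float((positions[j] - prev_pos) * direction)
        if ehh >= cutoff:
            area += d * (prev_ehh + ehh) / 2.0
            if ehh <= cutoff:  # landed exactly on the cutoff
                return area, True
            prev_ehh = ehh
            prev_pos = positions[j]
        else:
            # interpolate the crossing point and include it
            frac = (prev_ehh - cutoff) / (prev_ehh - ehh)
            area += d * frac * (prev_ehh + cutoff) / 2.0
            return area, True


@njit(cache=True)
def _ies_side(H, core, direction, cutoff, positions):
    """One-sided integral of EHHS (pooled homozygosity, normalized to 1 at
    the core).  Returns (area, complete)."""
    n = H.shape[0]
    m = H.shape[1]
    group = np.empty(n, np.int64)
    c1 = 0
    for t in range(n):
        group[t] = H[t, core]
        c1 += H[t, core]
    c0 = n - c1
    h0 = float(c0 * (c0 - 1) + c1 * (c1 - 1))
    if h0 <= 0:
        return 0.0, True
    keymap = np.full(2 * n + 2, -1, np.int64)
    tkeys = np.empty(2 * n + 2, np.int64)
    counts = np.zeros(n + 1, np.int64)
    ng = 2
    rows = np.arange(n)
    area = 0.0
    prev_ehh = 1.0
    prev_pos = positions[core]
    j = core
    while True:
        j += direction
        if j < 0 or j >= m:
            return area, False
        ng, s = _refine_step(H, rows, j, group, ng, keymap, tkeys, counts)
        ehh = s / h0
        d = float((positions[j] - prev_pos) * direction)
        if ehh >= cutoff:
            area += d * (prev_ehh + ehh) / 2.0
            if ehh <= cutoff:
                return area, True
            prev_ehh = ehh
            prev_pos = positions[j]
        else:
            frac = (prev_ehh - cutoff) / (prev_ehh - ehh)
            area += d * frac * (prev_ehh + cutoff) / 2.0
            return area, True


# site status codes shared by the scan kernels
_OK, _FEW_CARRIERS, _CENSORED, _ZERO_IHH = 0, 1, 2, 3


@njit(cache=True)
def _ihs_scan_kernel(H, positions, cutoff):
    n2, m = H.shape
    ihh_a = np.full(m, np.nan)
    ihh_d = np.full(m, np.nan)
    status = np.zeros(m, np.int8)
    for core in range(m):
        nd = 0
        for t in range(n2):
            nd += H[t, core]
        na = n2 - nd
        if na < 2 or nd < 2:
            status[core] = _FEW_CARRIERS
            continue
        rows_a = np.empty(na, np.int64)
        rows_d = np.empty(nd, np.int64)
        ia = 0
        idd = 0
        for t in range(n2):
            if H[t, core] == 0:
                rows_a[ia] = t
                ia += 1
            else:
                rows_d[idd] = t
                idd += 1
        aL, okAL = _ihh_side(H, rows_a, core, -1, cutoff, positions)
        aR, okAR = _ihh_side(H, rows_a, core, 1, cutoff, positions)
        dL, okDL = _ihh_side(H, rows_d, core, -1, cutoff, positions)
        dR, okDR = _ihh_side(H, rows_d, core, 1, cutoff, positions)
        if not (okAL and okAR and okDL and okDR):
            status[core] = _CENSORED
            continue
        a = aL + aR
        d = dL + dR
        if a <= 0.0 or d <= 0.0:
            status[core] = _ZERO_IHH
            continue
        ihh_a[core] = a
        ihh_d[core] = d
    return ihh_a, ihh_d, status


@njit(cache=True)
def _ies_scan_kernel(H, positions, cutoff):
    n2, m = H.shape
    ies_arr = np.full(m, np.nan)
    status = np.zeros(m, np.int8)
    for core in range(m):
        L, okL = _ies_side(H, core, -1, cutoff, positions)
        R, okR = _ies_side(H, core, 1, cutoff, positions)
        if not (okL and okR):
            status[core] = _CENSORED
            continue
        v = L + R
        if v <= 0.0:
            status[core] = _ZERO_IHH
            continue
        ies_arr[core] = v
    return ies_arr, status


# ---------------------------------------------------------------------------
# curve-level API
# ---------------------------------------------------------------------------


@dataclass
class EHHCurve:
    """EHH decay curve around one core site.

    ``core_allele`` is 0 (ancestral), 1 (derived) or -1 for the pooled
    EHHS curve.  Left/right arrays run outward from the core; the core
    itself (EHH = 1 at distance 0) is implicit.
    """

    core_position: int
    core_allele: int
    left_positions: np.ndarray
    left_ehh: np.ndarray
    right_positions: np.ndarray
    right_ehh: np.ndarray

    def side(self, direction: int) -> tuple[np.ndarray, np.ndarray]:
        if direction < 0:
            return self.left_positions, self.left_ehh
        return self.right_positions, self.right_ehh


def ehh(panel: HaplotypePanel, core_index: int, core_allele: int) -> EHHCurve:
    """EHH curve for one core site and allele (or pooled EHHS for
    ``core_allele = -1``), computed out to EHH = 0 or the chromosome edge."""
    H = panel.alleles
    positions = panel.positions
    m = panel.n_sites
    if not 0 <= core_index < m:
        raise IndexError("core_index out of range")
    sides = {}
    if core_allele == _POOLED:
        for direction in (-1, 1):
            ebuf = np.empty(m)
            pbuf = np.empty(m, np.int64)
            # reuse the curve kernel with explicit pooled normalization
            k = _ehhs_curve_side(H, core_index, direction, positions, ebuf, pbuf)
            sides[direction] = (pbuf[:k].copy(), ebuf[:k].copy())
    else:
        rows = np.flatnonzero(H[:, core_index] == core_allele)
        if rows.size < 2:
            raise ValueError(
                f"fewer than 2 carriers of allele {core_allele} at core {core_index}"
            )
        for direction in (-1, 1):
            ebuf = np.empty(m)
            pbuf = np.empty(m, np.int64)
            k = _curve_side(H, rows, core_index, direction, positions, ebuf, pbuf)
            sides[direction] = (pbuf[:k].copy(), ebuf[:k].copy())
    return EHHCurve(
        core_position=int(positions[core_index]),
        core_allele=core_allele,
        left_positions=sides[-1][0],
        left_ehh=sides[-1][1],
        right_positions=sides[1][0],
        right_ehh=sides[1][1],
    )


@njit(cache=True)
def _ehhs_curve_side(H, core, direction, positions, ehh_out, pos_out):
    n = H.shape[0]
    m = H.shape[1]
    group = np.empty(n, np.int64)
    c1 = 0
    for t in range(n):
        group[t] = H[t, core]
        c1 += H[t, core]
    c0 = n - c1
    h0 = float(c0 * (c0 - 1) + c1 * (c1 - 1))
    if h0 <= 0:
        return 0
    keymap = np.full(2 * n + 2, -1, np.int64)
    tkeys = np.empty(2 * n + 2, np.int64)
    counts = np.zeros(n + 1, np.int64)
    ng = 2
    rows = np.arange(n)
    k = 0
    j = core
    while True:
        j += direction
        if j < 0 or j >= m:
            return k
        ng, s = _refine_step(H, rows, j, group, ng, keymap, tkeys, counts)
        ehh_out[k] = s / h0
        pos_out[k] = positions[j]
        k += 1
        if s == 0:
            return k


def ihh(curve: EHHCurve, cutoff: float = DEFAULT_CUTOFF) -> tuple[float, bool]:
    """Integrate an EHH curve (both sides, trapezoid over base pairs).

    Integration stops at the first point where EHH drops below ``cutoff``
    (the interpolated crossing is included).  Returns ``(area, censored)``;
    ``censored`` is True when either side ends above the cutoff at the
    chromosome edge (such sites are excluded from standardization).
    """
    area = 0.0
    censored = False
    for direction in (-1, 1):
        pos, vals = curve.side(direction)
        prev_ehh = 1.0
        prev_pos = curve.core_position
        complete = pos.size == 0  # an empty side contributes nothing
        for p, e in zip(pos, vals):
            d = abs(int(p) - prev_pos)
            if e >= cutoff:
                area += d * (prev_ehh + e) / 2.0
                if e <= cutoff:
                    complete = True
                    break
                prev_ehh, prev_pos = e, int(p)
            else:
                frac = (prev_ehh - cutoff) / (prev_ehh - e)
                area += d * frac * (prev_ehh + cutoff) / 2.0
                complete = True
                break
        censored = censored or not complete
    return area, censored


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


@dataclass
class StandardizationBins:
    """Frequency-bin moments used to standardize a scan statistic."""

    edges: np.ndarray  # merged bin edges over derived-allele frequency
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray
    bin_of_site: np.ndarray  # merged-bin index per scored site

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                freq_lo=self.edges[:-1],
                freq_hi=self.edges[1:],
                mean=self.means,
                sd=self.sds,
                n=self.counts,
            )
        )


def _merge_bins(raw_bin: np.ndarray, n_edges: int, min_count: int) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent frequency bins until each has >= min_count sites.

    Left-to-right sweep: an undersized bin is merged into its right
    neighbour (the final bin merges leftward).  Returns (merged id per
    site, edge index array of merged-bin boundaries).
    """
    counts = np.bincount(raw_bin, minlength=n_edges - 1)
    groups: list[list[int]] = []
    cur: list[int] = []
    cur_n = 0
    for b in range(n_edges - 1):
        cur.append(b)
        cur_n += counts[b]
        if cur_n >= min_count:
            groups.append(cur)
            cur, cur_n = [], 0
    if cur:
        if groups:
            groups[-1].extend(cur)
        else:
            groups.append(cur)
    merged_of_raw = np.empty(n_edges - 1, dtype=np.int64)
    for gi, g in enumerate(groups):
        for b in g:
            merged_of_raw[b] = gi
    edges_idx = np.asarray([g[0] for g in groups] + [n_edges - 1], dtype=np.int64)
    return merged_of_raw[raw_bin], edges_idx


def _standardize_binned(
    unstd: np.ndarray, freqs: np.ndarray, bin_width: float, min_bin_count: int
) -> tuple[np.ndarray, StandardizationBins]:
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    raw_bin = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, edges.size - 2)
    bin_of_site, edge_idx = _merge_bins(raw_bin, edges.size, min_bin_count)
    n_bins = bin_of_site.max() + 1 if bin_of_site.size else 0
    means = np.empty(n_bins)
    sds = np.empty(n_bins)
    counts = np.empty(n_bins, dtype=np.int64)
    score = np.full(unstd.size, np.nan)
    for b in range(n_bins):
        sel = bin_of_site == b
        vals = unstd[sel]
        counts[b] = vals.size
        means[b] = vals.mean()
        sds[b] = vals.std()  # population (divide-by-n) SD
        if sds[b] > 0:
            score[sel] = (vals - means[b]) / sds[b]
    bins = StandardizationBins(
        edges=edges[edge_idx], means=means, sds=sds, counts=counts, bin_of_site=bin_of_site
    )
    return score, bins


def scan_pvalues(scores: np.ndarray) -> np.ndarray:
    """-log10 of the two-sided standard-normal p-value, per score."""
    scores = np.asarray(scores, dtype=float)
    with np.errstate(divide="ignore"):
        return -np.log10(2.0 * norm.sf(np.abs(scores)))


def _chrom_slices(chrom_ids: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous per-chromosome column ranges; scans never cross them."""
    n = len(chrom_ids)
    slices: list[tuple[int, int]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or chrom_ids[i] != chrom_ids[start]:
            slices.append((start, i))
            start = i
    seen = [chrom_ids[s] for s, _ in slices]
    if len(seen) != len(set(seen)):
        raise ValueError("chromosome columns must be contiguous")
    return slices


def ihs(
    panel: HaplotypePanel,
    population: str | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    freq_bin_width: float = 0.05,
    min_bin_count: int = 10,
    require_ancestral: bool = True,
) -> tuple[pd.DataFrame, StandardizationBins]:
    """Within-population iHS scan.

    ``panel`` must hold a single population (or pass ``population`` to
    subset).  EHH decay runs per chromosome; standardization pools sites
    genome-wide into derived-frequency bins.  Sites lacking
    ancestral-allele information are skipped when ``require_ancestral``
    (otherwise the reference allele is treated as ancestral, with a
    warning).  Returns a per-site table (chrom, pos, freq, ihh_a, ihh_d,
    unstandardized, score, neg_log10_p, status) and the frequency-bin
    moments; unscored sites carry a non-zero status (1 = <2 carriers of
    an allele, 2 = edge-censored, 3 = zero iHH, 4 = ancestral allele
    unknown).
    """
    if population is not None:
        panel = panel.for_population(population)
    pops = panel.populations
    if len(pops) > 1:
        raise ValueError("iHS is a within-population scan; subset the panel first")
    label = pops[0] if pops else ""

    H = panel.alleles
    m = panel.n_sites
    ihh_a = np.full(m, np.nan)
    ihh_d = np.full(m, np.nan)
    status = np.zeros(m, dtype=np.int8)
    for lo, hi in _chrom_slices(panel.chrom_ids):
        a, d, st = _ihs_scan_kernel(
            np.ascontiguousarray(H[:, lo:hi]), panel.positions[lo:hi], cutoff
        )
        ihh_a[lo:hi], ihh_d[lo:hi], status[lo:hi] = a, d, st
    status = status.astype(np.int16)
    if not panel.ancestral_known.all():
        if require_ancestral:
            status[~panel.ancestral_known] = 4
        else:
            warnings.warn(
                "treating the reference allele as ancestral at "
                f"{int((~panel.ancestral_known).sum())} unpolarized sites",
                stacklevel=2,
            )
    freqs = panel.derived_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        unstd = np.log(ihh_a / ihh_d)
    ok = (status == 0) & np.isfinite(unstd) & (freqs > 0) & (freqs < 1)

    score = np.full(panel.n_sites, np.nan)
    if ok.sum() >= 2:
        score_ok, bins = _standardize_binned(
            unstd[ok], freqs[ok], freq_bin_width, min_bin_count
        )
        score[ok] = score_ok
    else:
        bins = StandardizationBins(
            edges=np.asarray([0.0, 1.0]),
            means=np.empty(0),
            sds=np.empty(0),
            counts=np.empty(0, dtype=np.int64),
            bin_of_site=np.empty(0, dtype=np.int64),
        )
    table = pd.DataFrame(
        dict(
            chrom=panel.chrom_ids,
            pos=panel.positions,
            freq=freqs,
            ihh_a=ihh_a,
            ihh_d=ihh_d,
            unstandardized=unstd,
            score=score,
            neg_log10_p=scan_pvalues(score),
            status=status,
            population=label,
        )
    )
    return table, bins


def ies(panel: HaplotypePanel, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Per-site iES (integrated EHHS) for one population.

    Returns a table (chrom, pos, ies, status); Rsb needs no allele
    polarity, so all fully polymorphic sites are usable.
    """
    pops = panel.populations
    if len(pops) > 1:
        raise ValueError("iES is computed within one population; subset first")
    m = panel.n_sites
    ies_arr = np.full(m, np.nan)
    status = np.zeros(m, dtype=np.int8)
    for lo, hi in _chrom_slices(panel.chrom_ids):
        v, st = _ies_scan_kernel(
            np.ascontiguousarray(panel.alleles[:, lo:hi]), panel.positions[lo:hi], cutoff
        )
        ies_arr[lo:hi], status[lo:hi] = v, st
    return pd.DataFrame(
        dict(chrom=panel.chrom_ids, pos=panel.positions, ies=ies_arr, status=status)
    )


def rsb(
    ies_pop1: pd.DataFrame,
    ies_pop2: pd.DataFrame,
    populations: tuple[str, str] = ("pop1", "pop2"),
) -> pd.DataFrame:
    """Cross-population Rsb scan from two per-site iES tables.

    Joins on (chrom, pos), takes ln(iES_pop1 / iES_pop2) and standardizes
    genome-wide (single bin: Rsb uses no allele polarity, so there is no
    frequency binning).  Positive scores attribute candidate selection to
    ``populations[0]``, negative to ``populations[1]``.
    """
    merged = ies_pop1.merge(
        ies_pop2, on=["chrom", "pos"], suffixes=("_1", "_2"), how="inner"
    )
    ok = (
        (merged["status_1"] == 0)
        & (merged["status_2"] == 0)
        & (merged["ies_1"] > 0)
        & (merged["ies_2"] > 0)
    ).to_numpy()
    unstd = np.full(len(merged), np.nan)
    unstd[ok] = np.log(
        merged.loc[ok, "ies_1"].to_numpy() / merged.loc[ok, "ies_2"].to_numpy()
    )
    score = np.full(len(merged), np.nan)
    vals = unstd[ok]
    if vals.size >= 2 and vals.std() > 0:
        score[ok] = (vals - vals.mean()) / vals.std()
    out = pd.DataFrame(
        dict(
            chrom=merged["chrom"],
            pos=merged["pos"],
            unstandardized=unstd,
            score=score,
            neg_log10_p=scan_pvalues(score),
        )
    )
    out["population"] = np.where(out["score"] > 0, populations[0], populations[1])
    out.loc[~np.isfinite(out["score"]), "population"] = ""
    out.attrs["populations"] = populations
    return out
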