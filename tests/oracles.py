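"""Independent brute-force / closed-form oracles used only by the tests.

Each function is a direct transcription of the defining formula or an
explicit enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_ehh(H: np.ndarray, rows: np.ndarray, core: int, target: int) -> float:
    """EHH by enumerating all carrier pairs: the fraction identical over
    every column between core and target (inclusive)."""
    lo, hi = min(core, target), max(core, target)
    rows = list(rows)
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 carriers")
    same = 0
    for i, j in itertools.combinations(range(n), 2):
        if np.array_equal(H[rows[i], lo : hi + 1], H[rows[j], lo : hi + 1]):
            same += 1
    return same / (n * (n - 1) / 2)


def brute_force_ehhs(H: np.ndarray, core: int, target: int) -> float:
    """Pooled haplotype homozygosity over [core, target], normalized to 1
    at the core, by pair enumeration over all chromosomes."""

    def hom(lo: int, hi: int) -> float:
        n = H.shape[0]
        same = 0
        for i, j in itertools.combinations(range(n), 2):
            if np.array_equal(H[i, lo : hi + 1], H[j, lo : hi + 1]):
                same += 1
        return same / (n * (n - 1) / 2)

    h0 = hom(core, core)
    lo, hi = min(core, target), max(core, target)
    return hom(lo, hi) / h0


def pairwise_pi(H: np.ndarray, length: int) -> float:
    """Mean pairwise Hamming distance per base pair over all haplotype
    pairs (direct pair enumeration)."""
    n = H.shape[0]
    total = 0
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((H[i] != H[j]).sum())
        npairs += 1
    return total / npairs / length


def wc_theta_oracle(counts_by_pop: list[tuple[int, int, int]]) -> tuple[float, float, float, float]:
    """Weir & Cockerham (1984) a, b, c and theta from per-population
    genotype counts (n_AA, n_Aa, n_aa), transcribed term by term."""
    r = len(counts_by_pop)
    n_i, p_i, h_i = [], [], []
    for n_AA, n_Aa, n_aa in counts_by_pop:
        n = n_AA + n_Aa + n_aa
        n_i.append(n)
        p_i.append((2 * n_aa + n_Aa) / (2 * n))
        h_i.append(n_Aa / n)
    n_bar = sum(n_i) / r
    n_c = (r * n_bar - sum(n**2 for n in n_i) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (1 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return a, b, c, theta


def hwe_p_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg p by the recurrence over heterozygote counts
    (conditional on allele counts), independent of the gammaln route."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    hets = list(range(rare % 2, rare + 1, 2))
    # unnormalized probabilities via the ratio
    # P(h+2)/P(h) = 4 * hom_rare(h) * hom_common(h) / ((h+2)(h+1))
    probs = {hets[0]: 1.0}
    for h in hets[:-1]:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h + 2] = probs[h] * 4.0 * hom_rare * hom_common / ((h + 2) * (h + 1))
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return min(1.0, sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-9)))


def silhouette(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (explicit pairwise distances)."""
    labels = np.asarray(labels)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(len(labels)):
        same = (labels == labels[i]) & (np.arange(len(labels)) != i)
        a = d[i, same].mean()
        b = min(d[i, labels == other].mean() for other in set(labels) - {labels[i]})
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def nearest_centroid_purity(coords: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of samples whose nearest population centroid is their own."""
    labels = np.asarray(labels)
    cents = {l: coords[labels == l].mean(axis=0) for l in set(labels)}
    keys = list(cents)
    hits = 0
    for i in range(len(labels)):
        d = [np.linalg.norm(coords[i] - cents[k]) for k in keys]
        hits += keys[int(np.argmin(d))] == labels[i]
    return hits / len(labels)
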