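"""Diversity, LD, Weir-Cockerham F_ST and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import selsweep as ss
from selsweep.popstats import (
    heterozygosity,
    ld_r2_decay,
    mean_weighted_fst,
    nucleotide_diversity_windows,
    pca,
    site_pi,
    wc_fst_components,
    wc_fst_per_snp,
    wc_fst_windows,
)

from oracles import nearest_centroid_purity, pairwise_pi, silhouette, wc_theta_oracle


# ---------------------------------------------------------------------------
# heterozygosity / pi
# ---------------------------------------------------------------------------

def test_heterozygosity_worked_examples():
    all_het = np.ones((6, 1), dtype=np.int8)
    assert heterozygosity(all_het) == (1.0, 0.5)
    mono = np.zeros((6, 1), dtype=np.int8)
    assert heterozygosity(mono) == (0.0, 0.0)
    toy = np.array([[0], [1], [1], [2]], dtype=np.int8)  # AA, Aa, Aa, aa
    ho, he = heterozygosity(toy)
    assert ho == pytest.approx(0.5)
    assert he == pytest.approx(0.5)


def test_single_snp_window_pi():
    # one SNP, two called alleles (k=2, j=1), 1 kb window -> pi = 0.001
    g = np.array([[1]], dtype=np.int8)  # one diploid het: k=2, j=1
    win = nucleotide_diversity_windows(
        g, np.array([500]), np.array(["1"], dtype=object), {"1": 1000},
        window=1000, step=1000,
    )
    assert win.loc[0, "value"] == pytest.approx(1 / 1000)


def test_empty_window_pi_is_zero():
    g = np.array([[1]], dtype=np.int8)
    win = nucleotide_diversity_windows(
        g, np.array([500]), np.array(["1"], dtype=object), {"1": 3000},
        window=1000, step=1000,
    )
    assert win.loc[1, "value"] == 0.0 and win.loc[2, "value"] == 0.0


def test_windowed_pi_matches_brute_force_pairwise(small_neutral_panels):
    """Non-overlapping windowed pi reconciles exactly with the direct
    pairwise Hamming-distance oracle over the whole chromosome."""
    panel = small_neutral_panels[0]
    L = panel.chrom_length("1")
    win = nucleotide_diversity_windows(
        panel.genotypes(), panel.positions, panel.chrom_ids, {"1": L},
        window=L, step=L,
    )
    brute = pairwise_pi(panel.alleles, L)
    assert win.loc[0, "value"] == pytest.approx(brute, abs=1e-9)


def test_window_smaller_than_step_rejected():
    g = np.array([[1]], dtype=np.int8)
    with pytest.raises(ValueError):
        nucleotide_diversity_windows(
            g, np.array([1]), np.array(["1"], dtype=object), window=100, step=200
        )


def test_pi_conservation_over_nonoverlapping_windows(small_neutral_panels):
    panel = small_neutral_panels[1]
    L = panel.chrom_length("1")
    win = nucleotide_diversity_windows(
        panel.genotypes(), panel.positions, panel.chrom_ids, {"1": L},
        window=10_000, step=10_000,
    )
    total = (win["value"] * (win["end"] - win["start"] + 1)).sum()
    assert total == pytest.approx(site_pi(panel.genotypes()).sum(), rel=1e-9)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def _ld_of_haplotype_counts(ab, aB, Ab, AB):
    """Build explicit haplotypes from two-locus counts and bin them."""
    rows = ([[1, 1]] * AB) + ([[1, 0]] * Ab) + ([[0, 1]] * aB) + ([[0, 0]] * ab)
    H = np.array(rows, dtype=np.uint8)
    return ld_r2_decay(H, np.array([100, 200]), max_dist=1000, bin_width=1000)


def test_ld_worked_examples():
    # perfect LD
    out = _ld_of_haplotype_counts(ab=5, aB=0, Ab=0, AB=5)
    assert out.loc[0, "mean_r2"] == pytest.approx(1.0)
    # independence at equal haplotype counts
    out = _ld_of_haplotype_counts(ab=1, aB=1, Ab=1, AB=1)
    assert out.loc[0, "mean_r2"] == pytest.approx(0.0, abs=1e-12)
    # AB=4, Ab=1, aB=1, ab=4 -> D = 0.4 - 0.25 = 0.15 -> r2 = 0.15^2/0.5^4
    out = _ld_of_haplotype_counts(ab=4, aB=1, Ab=1, AB=4)
    assert out.loc[0, "mean_r2"] == pytest.approx(0.36)


def test_ld_monomorphic_pairs_skipped():
    H = np.array([[1, 1], [1, 0], [1, 1]], dtype=np.uint8)
    out = ld_r2_decay(H, np.array([10, 20]), max_dist=100, bin_width=100)
    assert out.loc[0, "n_pairs"] == 0


def test_ld_decay_is_decreasing_on_neutral_panels(small_neutral_panels):
    """Mean r^2 falls over the first distance bins under recombination."""
    firsts, laters = [], []
    for panel in small_neutral_panels:
        out = ld_r2_decay(panel.alleles, panel.positions, max_dist=60_000, bin_width=20_000)
        if (out["n_pairs"] > 0).all():
            firsts.append(out["mean_r2"].iloc[0])
            laters.append(out["mean_r2"].iloc[2])
    assert np.mean(firsts) > np.mean(laters)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _geno_from_counts(n_AA, n_Aa, n_aa):
    return np.array([0] * n_AA + [1] * n_Aa + [2] * n_aa, dtype=np.int8).reshape(-1, 1)


def test_fst_complete_fixation_is_one():
    comp = wc_fst_per_snp(_geno_from_counts(10, 0, 0), _geno_from_counts(0, 0, 10))
    assert comp.loc[0, "theta"] == pytest.approx(1.0)


def test_fst_identical_populations_nonpositive():
    g = _geno_from_counts(6, 3, 1)
    comp = wc_fst_per_snp(g, g.copy())
    assert comp.loc[0, "theta"] <= 0


def test_fst_matches_independent_transcription_worked_case():
    comp = wc_fst_per_snp(_geno_from_counts(6, 3, 1), _geno_from_counts(1, 3, 6))
    a, b, c, theta = wc_theta_oracle([(6, 3, 1), (1, 3, 6)])
    assert comp.loc[0, "a"] == pytest.approx(a, abs=1e-12)
    assert comp.loc[0, "b"] == pytest.approx(b, abs=1e-12)
    assert comp.loc[0, "c"] == pytest.approx(c, abs=1e-12)
    assert comp.loc[0, "theta"] == pytest.approx(theta, abs=1e-12)


def test_fst_matches_oracle_on_random_configurations():
    """1,000 random two-population genotype configurations, 1e-12 agreement."""
    rng = np.random.default_rng(12)
    for _ in range(1000):
        ca = tuple(rng.integers(0, 15, size=3))
        cb = tuple(rng.integers(0, 15, size=3))
        if sum(ca) < 2 or sum(cb) < 2:
            continue
        comp = wc_fst_per_snp(_geno_from_counts(*ca), _geno_from_counts(*cb))
        a, b, c, theta = wc_theta_oracle([ca, cb])
        assert comp.loc[0, "a"] == pytest.approx(a, abs=1e-12)
        got = comp.loc[0, "theta"]
        if np.isnan(theta):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(theta, abs=1e-12)


def test_fst_monomorphic_site_flagged():
    comp = wc_fst_per_snp(_geno_from_counts(5, 0, 0), _geno_from_counts(7, 0, 0))
    assert np.isnan(comp.loc[0, "theta"])


def test_fst_window_is_ratio_of_sums_not_mean():
    ga = np.hstack([_geno_from_counts(6, 3, 1), _geno_from_counts(10, 0, 0),
                    _geno_from_counts(2, 5, 3)])
    gb = np.hstack([_geno_from_counts(1, 3, 6), _geno_from_counts(0, 0, 10),
                    _geno_from_counts(3, 5, 2)])
    comp = wc_fst_per_snp(ga, gb)
    win = wc_fst_windows(
        comp, np.array([100, 200, 300]), np.array(["1"] * 3, dtype=object),
        {"1": 400}, window=400, step=400,
    )
    abc = comp[["a", "b", "c"]].sum(axis=1)
    expected = comp["a"].sum() / abc.sum()
    assert win.loc[0, "value"] == pytest.approx(expected, abs=1e-12)
    assert win.loc[0, "value"] != pytest.approx(comp["theta"].mean(), abs=1e-6)
    assert win.loc[0, "n_snps"] == 3


def test_fst_window_single_snp_equals_theta():
    comp = wc_fst_per_snp(_geno_from_counts(6, 3, 1), _geno_from_counts(1, 3, 6))
    win = wc_fst_windows(
        comp, np.array([100]), np.array(["1"], dtype=object), {"1": 200},
        window=200, step=200,
    )
    assert win.loc[0, "value"] == pytest.approx(comp.loc[0, "theta"], abs=1e-12)


def test_fst_all_fixed_windows_value_one():
    ga = np.hstack([_geno_from_counts(8, 0, 0)] * 3)
    gb = np.hstack([_geno_from_counts(0, 0, 8)] * 3)
    comp = wc_fst_per_snp(ga, gb)
    win = wc_fst_windows(
        comp, np.array([10, 20, 30]), np.array(["1"] * 3, dtype=object),
        {"1": 100}, window=100, step=100,
    )
    assert win.loc[0, "value"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# allele-label invariance (site-wise 0/2 swap)
# ---------------------------------------------------------------------------

@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_statistics_invariant_to_allele_relabeling(seed):
    rng = np.random.default_rng(seed)
    n, m = 12, 8
    ga = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    gb = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    flip = rng.random(m) < 0.5
    ga_f = np.where(flip, 2 - ga, ga).astype(np.int8)
    gb_f = np.where(flip, 2 - gb, gb).astype(np.int8)

    np.testing.assert_allclose(site_pi(ga), site_pi(ga_f), atol=1e-12)
    assert heterozygosity(ga)[1] == pytest.approx(heterozygosity(ga_f)[1], abs=1e-12)
    t1 = wc_fst_per_snp(ga, gb)["theta"].to_numpy()
    t2 = wc_fst_per_snp(ga_f, gb_f)["theta"].to_numpy()
    np.testing.assert_allclose(t1, t2, atol=1e-12)


def test_r2_invariant_to_allele_relabeling():
    rng = np.random.default_rng(5)
    H = rng.integers(0, 2, size=(30, 6)).astype(np.uint8)
    pos = np.arange(1, 7) * 10
    flip = rng.random(6) < 0.5
    Hf = np.where(flip, 1 - H, H).astype(np.uint8)
    a = ld_r2_decay(H, pos, 100, 100)
    b = ld_r2_decay(Hf, pos, 100, 100)
    assert a.loc[0, "mean_r2"] == pytest.approx(b.loc[0, "mean_r2"], abs=1e-12)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_duplicate_samples_coincide_and_eigs_sorted():
    rng = np.random.default_rng(8)
    g = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    g[1] = g[0]
    eigvals, coords, pct = pca(g)
    np.testing.assert_allclose(coords[0], coords[1], atol=1e-8)
    assert (np.diff(eigvals) <= 1e-9).all()
    assert (eigvals >= -1e-9).all()


def test_pca_separates_split_populations(split3_panels):
    """Three-way splits resolve into three clusters on the first two PCs
    (nearest-centroid purity > 0.9, positive silhouette)."""
    for panel in split3_panels:
        _, coords, _ = pca(panel.genotypes())
        labels = np.array([panel.population_of[s] for s in panel.sample_ids])
        xy = coords[:, :2]
        assert nearest_centroid_purity(xy, labels) > 0.9
        assert silhouette(xy, labels) > 0
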