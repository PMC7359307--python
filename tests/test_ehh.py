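"""EHH curves, iHH integration, iHS/iES/Rsb scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import selsweep as ss
from selsweep.ehh import EHHCurve, ehh, ihh, ihs, ies, rsb, scan_pvalues

from conftest import maf_filter
from oracles import brute_force_ehh, brute_force_ehhs


def _panel(H, positions=None, pop="A"):
    H = np.asarray(H, dtype=np.uint8)
    n = H.shape[0] // 2
    m = H.shape[1]
    positions = np.asarray(positions if positions is not None else np.arange(1, m + 1) * 100)
    samples = [f"s{i}" for i in range(n)]
    return ss.HaplotypePanel(
        alleles=H, positions=positions,
        chrom_ids=np.asarray(["1"] * m, dtype=object),
        sample_ids=samples, population_of={s: pop for s in samples},
        ancestral_known=np.ones(m, dtype=bool),
    )


# ---------------------------------------------------------------------------
# EHH curves
# ---------------------------------------------------------------------------

def test_ehh_four_carriers_splitting_two_and_two():
    # 4 derived carriers split 2+2 at the next site: EHH = (1+1)/C(4,2) = 1/3
    H = np.array(
        [
            [1, 0], [1, 0], [1, 1], [1, 1],  # carriers
            [0, 0], [0, 1],
        ],
        dtype=np.uint8,
    )
    curve = ehh(_panel(H), core_index=0, core_allele=1)
    assert curve.right_ehh[0] == pytest.approx(1 / 3)


def test_ehh_identical_carriers_stay_at_one():
    H = np.zeros((6, 5), dtype=np.uint8)
    H[:4] = 1  # carriers identical everywhere
    H[4, 2] = 1  # keep site 2 informative for non-carriers
    curve = ehh(_panel(H), core_index=0, core_allele=1)
    assert (curve.right_ehh == 1.0).all()


def test_ehh_needs_two_carriers():
    H = np.array([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.uint8)
    with pytest.raises(ValueError):
        ehh(_panel(H), core_index=0, core_allele=1)


def test_ehh_matches_brute_force_enumeration():
    """Exact (1e-12) agreement with all-pairs enumeration on random panels."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(4, 13))
        m = int(rng.integers(3, 21))
        H = rng.integers(0, 2, size=(2 * ((n + 1) // 2), m)).astype(np.uint8)
        core = int(rng.integers(0, m))
        panel = _panel(H)
        idx_of_pos = {int(p): j for j, p in enumerate(panel.positions)}
        for allele in (0, 1):
            rows = np.flatnonzero(H[:, core] == allele)
            if rows.size < 2:
                continue
            curve = ehh(panel, core, allele)
            for direction in (-1, 1):
                pos, vals = curve.side(direction)
                for p, v in zip(pos, vals):
                    want = brute_force_ehh(H, rows, core, idx_of_pos[int(p)])
                    assert v == pytest.approx(want, abs=1e-12)


def test_ehh_curves_monotone_nonincreasing():
    rng = np.random.default_rng(9)
    H = rng.integers(0, 2, size=(12, 15)).astype(np.uint8)
    panel = _panel(H)
    for core in range(15):
        for allele in (0, 1):
            if np.flatnonzero(H[:, core] == allele).size < 2:
                continue
            curve = ehh(panel, core, allele)
            for _, vals in (curve.side(-1), curve.side(1)):
                assert (np.diff(vals) <= 1e-12).all()
                assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()


def test_ehhs_brackets_allele_specific_ehh():
    """Pooled EHHS is a convex combination of the allele-specific curves."""
    rng = np.random.default_rng(17)
    for _ in range(30):
        H = rng.integers(0, 2, size=(8, 10)).astype(np.uint8)
        core = int(rng.integers(0, 10))
        n1 = H[:, core].sum()
        if n1 < 2 or 8 - n1 < 2:
            continue
        for target in range(10):
            es = brute_force_ehhs(H, core, target)
            e0 = brute_force_ehh(H, np.flatnonzero(H[:, core] == 0), core, target)
            e1 = brute_force_ehh(H, np.flatnonzero(H[:, core] == 1), core, target)
            assert min(e0, e1) - 1e-12 <= es <= max(e0, e1) + 1e-12


def test_ehhs_curve_matches_brute_force():
    rng = np.random.default_rng(21)
    H = rng.integers(0, 2, size=(8, 12)).astype(np.uint8)
    panel = _panel(H)
    for core in (0, 5, 11):
        if H[:, core].sum() in (0, 8):
            continue
        curve = ehh(panel, core, -1)
        for direction in (-1, 1):
            pos, vals = curve.side(direction)
            for p, v in zip(pos, vals):
                j = int(np.flatnonzero(panel.positions == p)[0])
                assert v == pytest.approx(brute_force_ehhs(H, core, j), abs=1e-12)


# ---------------------------------------------------------------------------
# iHH integration
# ---------------------------------------------------------------------------

def _one_sided_curve(points):
    pos = np.array([p for p, _ in points])
    vals = np.array([v for _, v in points])
    return EHHCurve(
        core_position=0, core_allele=1,
        left_positions=np.empty(0, dtype=np.int64), left_ehh=np.empty(0),
        right_positions=pos, right_ehh=vals,
    )


def test_ihh_hand_trapezoid():
    # {0: 1.0, 10 kb: 0.5, 20 kb: 0.05} -> 10000*0.75 + 10000*0.275 = 10250
    curve = _one_sided_curve([(10_000, 0.5), (20_000, 0.05)])
    area, censored = ihh(curve, cutoff=0.05)
    assert area == pytest.approx(10_250.0)
    assert not censored


def test_ihh_flat_top_lower_bound():
    curve = _one_sided_curve([(5_000, 1.0), (5_001, 0.0)])
    area, censored = ihh(curve, cutoff=0.05)
    assert area >= 5_000
    assert not censored


def test_ihh_degenerate_cutoff_one():
    curve = _one_sided_curve([(10_000, 0.5)])
    area, _ = ihh(curve, cutoff=1.0)
    assert area == 0.0


def test_ihh_censored_when_curve_ends_above_cutoff():
    curve = _one_sided_curve([(10_000, 0.5)])
    area, censored = ihh(curve, cutoff=0.05)
    assert censored


def test_ihh_interpolates_crossing_point():
    # 1.0 at 0, 0.0 at 1000, cutoff 0.5: crossing at 500;
    # area = 500 * (1 + 0.5)/2 = 375
    curve = _one_sided_curve([(1_000, 0.0)])
    area, censored = ihh(curve, cutoff=0.5)
    assert area == pytest.approx(375.0)
    assert not censored


def test_scan_ihh_consistent_with_curve_route(small_sweep):
    """The fused scan kernel equals ehh() + ihh() composition."""
    panel, _ = small_sweep
    sub = maf_filter(panel).subset_sites(np.arange(200))
    scores, _ = ihs(sub)
    scored = scores.dropna(subset=["unstandardized"]).head(25)
    for idx, row in scored.iterrows():
        ca, _ = ihh(ehh(sub, idx, 0))
        cd, _ = ihh(ehh(sub, idx, 1))
        assert row["ihh_a"] == pytest.approx(ca, rel=1e-9)
        assert row["ihh_d"] == pytest.approx(cd, rel=1e-9)


# ---------------------------------------------------------------------------
# iHS / iES / Rsb
# ---------------------------------------------------------------------------

def test_ihs_bin_standardization_two_point():
    vals = np.array([2.0, 4.0])
    std = (vals - vals.mean()) / vals.std()
    np.testing.assert_allclose(std, [-1.0, 1.0])


def test_ihs_bins_have_zero_mean_unit_sd(small_sweep):
    panel, _ = small_sweep
    scores, bins = ihs(maf_filter(panel))
    ok = scores["score"].notna().to_numpy()
    u = scores.loc[ok, "unstandardized"].to_numpy()
    z = scores.loc[ok, "score"].to_numpy()
    for b in range(bins.means.size):
        sel = bins.bin_of_site == b
        if bins.sds[b] > 0:
            assert z[sel].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[sel].std() == pytest.approx(1.0, abs=1e-9)
        assert u[sel].mean() == pytest.approx(bins.means[b], abs=1e-9)


def test_ihs_requires_single_population(split3_panels):
    with pytest.raises(ValueError):
        ihs(split3_panels[0])


def test_ihs_scores_invariant_to_sample_order(small_sweep):
    panel, _ = small_sweep
    sub = maf_filter(panel).subset_sites(np.arange(150))
    scores1, _ = ihs(sub)
    order = np.random.default_rng(3).permutation(sub.n_samples)
    rows = np.empty(2 * order.size, dtype=np.int64)
    rows[0::2] = 2 * order
    rows[1::2] = 2 * order + 1
    shuffled = ss.HaplotypePanel(
        alleles=sub.alleles[rows],
        positions=sub.positions, chrom_ids=sub.chrom_ids,
        sample_ids=[sub.sample_ids[i] for i in order],
        population_of=sub.population_of,
        ancestral_known=sub.ancestral_known,
        chrom_lengths=sub.chrom_lengths,
    )
    scores2, _ = ihs(shuffled)
    np.testing.assert_allclose(
        scores1["score"].to_numpy(), scores2["score"].to_numpy(),
        atol=1e-9, equal_nan=True,
    )


def test_ies_all_identical_haplotypes_spans_scanned_length():
    H = np.zeros((8, 3), dtype=np.uint8)
    H[:, 1] = [1, 1, 1, 1, 0, 0, 0, 0]
    H[:4, 0] = 0  # sites 0 and 2 monomorphic -> haplotypes identical within groups
    panel = _panel(H, positions=[100, 200, 300])
    # at the central core, both allele classes are internally identical:
    # EHHS stays 1 to both ends -> integral = full scanned span (200 bp),
    # and the site is edge-censored (the curve never decays to the cutoff)
    curve = ehh(panel, 1, -1)
    area, censored = ihh(curve, cutoff=0.05)
    assert area == pytest.approx(200.0)
    assert censored
    out = ies(panel, cutoff=0.0)
    assert np.isnan(out.loc[1, "ies"]) and out.loc[1, "status"] == 2


def test_rsb_identical_panels_zero_and_antisymmetry(small_sweep):
    panel, _ = small_sweep
    sub = maf_filter(panel).subset_sites(np.arange(300))
    t = ies(sub)
    same = rsb(t, t.copy(), populations=("A", "B"))
    ok = same["unstandardized"].notna()
    np.testing.assert_allclose(same.loc[ok, "unstandardized"], 0.0, atol=1e-12)

    # antisymmetry against a perturbed copy
    t2 = t.copy()
    t2["ies"] = t2["ies"] * np.linspace(0.5, 2.0, len(t2))
    fwd = rsb(t, t2, populations=("A", "B"))
    rev = rsb(t2, t, populations=("B", "A"))
    np.testing.assert_allclose(
        fwd["unstandardized"].to_numpy(), -rev["unstandardized"].to_numpy(),
        atol=1e-12, equal_nan=True,
    )
    np.testing.assert_allclose(
        fwd["score"].to_numpy(), -rev["score"].to_numpy(), atol=1e-9, equal_nan=True
    )


def test_scan_pvalues_worked_examples():
    assert scan_pvalues(np.array([0.0]))[0] == pytest.approx(0.0)
    assert scan_pvalues(np.array([1.959964]))[0] == pytest.approx(1.301, abs=1e-3)
    z = np.array([0.5, 1.0, 2.0, 4.0])
    assert (np.diff(scan_pvalues(z)) > 0).all()


def test_multi_chromosome_scan_stops_at_boundaries(small_neutral_panels):
    """On a concatenated panel, per-site iHH values equal those from
    scanning each chromosome separately; standardization pools both."""
    import dataclasses

    a = maf_filter(small_neutral_panels[0])
    b0 = maf_filter(small_neutral_panels[1])
    b = dataclasses.replace(
        b0, chrom_ids=np.asarray(["2"] * b0.n_sites, dtype=object),
        chrom_lengths={"2": 100_000},
    )
    b.sample_ids = list(a.sample_ids)
    b.population_of = dict(a.population_of)
    combo = ss.concat_panels([a, b])
    got, _ = ihs(combo)
    sep_a, _ = ihs(a)
    sep_b, _ = ihs(b)
    np.testing.assert_allclose(
        got.loc[got["chrom"] == "1", "unstandardized"].to_numpy(),
        sep_a["unstandardized"].to_numpy(), atol=1e-12, equal_nan=True,
    )
    np.testing.assert_allclose(
        got.loc[got["chrom"] == "2", "unstandardized"].to_numpy(),
        sep_b["unstandardized"].to_numpy(), atol=1e-12, equal_nan=True,
    )
    ies_combo = ies(combo)
    np.testing.assert_allclose(
        ies_combo.loc[ies_combo["chrom"] == "2", "ies"].to_numpy(),
        ies(b)["ies"].to_numpy(), atol=1e-12, equal_nan=True,
    )
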