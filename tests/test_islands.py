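import numpy as np
import pandas as pd
import pytest

from rohscan.islands import (IslandConfig, call_islands, incidence_matrix,
                             shared_islands, zscore_scan)

from _oracles import brute_force_incidence
from test_inbreeding import map_frame, sample_table, seg_frame


def hd_map(n=300, spacing=10_000, chrom="1"):
    return map_frame([(chrom, list(range(spacing, (n + 1) * spacing, spacing)))])


def test_identical_segments_give_population_size_inside_zero_outside():
    samples = sample_table([("a", "P"), ("b", "P"), ("c", "P")])
    seg = seg_frame([(s, "P", "1", 500_000, 1_500_000) for s in "abc"])
    counts = incidence_matrix(seg, hd_map(), samples, "P")
    inside = counts[(counts["pos"] >= 500_000) & (counts["pos"] <= 1_500_000)]
    outside = counts[(counts["pos"] < 500_000) | (counts["pos"] > 1_500_000)]
    assert (inside["count"] == 3).all()
    assert (outside["count"] == 0).all()


def test_single_individual_segment_is_an_indicator_vector():
    samples = sample_table([("a", "P")])
    seg = seg_frame([("a", "P", "1", 100_000, 400_000)])
    counts = incidence_matrix(seg, hd_map(), samples, "P")
    assert counts["count"].sum() == ((counts["pos"] >= 100_000)
                                     & (counts["pos"] <= 400_000)).sum() == 31


def test_incidence_matches_brute_force_double_loop():
    rng = np.random.default_rng(3)
    snp_map = hd_map(n=200)
    pos = snp_map["pos"].to_numpy()
    names = [f"i{k}" for k in range(20)]
    samples = sample_table([(n, "P") for n in names])
    rows = []
    for name in names:
        cursor = 0
        for _ in range(rng.integers(0, 4)):
            # segments of one individual never overlap
            a = cursor + int(rng.integers(0, 40))
            b = a + int(rng.integers(1, 10))
            if b > 199:
                break
            rows.append((name, "P", "1", int(pos[a]), int(pos[b])))
            cursor = b + 2
    seg = seg_frame(rows)
    counts = incidence_matrix(seg, snp_map, samples, "P")
    expected = brute_force_incidence(seg, pos, names)
    np.testing.assert_array_equal(counts["count"].to_numpy(), expected)


def test_incidence_invariant_to_segment_and_sample_order():
    samples = sample_table([("a", "P"), ("b", "P")])
    rows = [("a", "P", "1", 100_000, 900_000), ("b", "P", "1", 400_000, 1_200_000)]
    c1 = incidence_matrix(seg_frame(rows), hd_map(), samples, "P")
    c2 = incidence_matrix(seg_frame(rows[::-1]), hd_map(), samples.iloc[::-1], "P")
    np.testing.assert_array_equal(c1["count"].to_numpy(), c2["count"].to_numpy())


def test_uniform_incidence_has_zero_sd_and_no_islands():
    counts = pd.DataFrame({"chrom": "1", "snp": [f"s{i}" for i in range(50)],
                           "pos": np.arange(1, 51) * 10_000, "count": 2})
    with pytest.warns(UserWarning, match="uniform"):
        scan = zscore_scan(counts, population_size=4)
    assert not scan.table["significant"].any()
    assert np.isnan(scan.threshold_pct)


def test_zscore_of_extreme_snp_matches_independent_arithmetic():
    counts = pd.DataFrame({"chrom": "1", "snp": [f"s{i}" for i in range(10)],
                           "pos": np.arange(1, 11) * 10_000,
                           "count": [0] * 9 + [5]})
    scan = zscore_scan(counts, population_size=5)
    pct = np.array([0.0] * 9 + [100.0])
    z_expected = (100.0 - pct.mean()) / pct.std()
    assert scan.table["z"].iloc[-1] == pytest.approx(z_expected)


def test_critical_z_for_default_tail_is_4_2649():
    """One-sided upper-tail p < 1e-5 corresponds to z >= 4.2649."""
    assert IslandConfig().z_critical == pytest.approx(4.2649, abs=1e-4)


def test_lowering_tail_fraction_never_adds_significant_snps():
    rng = np.random.default_rng(11)
    counts = pd.DataFrame({"chrom": "1", "snp": [f"s{i}" for i in range(500)],
                           "pos": np.arange(1, 501) * 10_000,
                           "count": rng.integers(0, 30, size=500)})
    n_prev = None
    for tail in (1e-2, 1e-3, 1e-5, 1e-7):
        scan = zscore_scan(counts, 30, IslandConfig(tail_fraction=tail))
        n = int(scan.table["significant"].sum())
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def _scan_with_significant(positions, sig_positions, chrom="1"):
    """Build an IslandScan-like object via zscore_scan with a forced tail."""
    counts = pd.DataFrame({"chrom": chrom, "snp": [f"s{p}" for p in positions],
                           "pos": positions,
                           "count": [10 if p in set(sig_positions) else 0
                                     for p in positions]})
    return zscore_scan(counts, 10, IslandConfig(tail_fraction=0.05, min_island_snps=2))


def test_contiguous_significant_snps_form_one_island():
    sig = list(range(10_000, 1_210_000, 24_000))  # 50 SNPs over ~1.2 Mb
    background = list(range(5_000_000, 20_000_000, 24_000))
    allpos = sig + background
    scan = _scan_with_significant(allpos, sig)
    isl = call_islands(scan, map_frame([("1", allpos)]),
                       IslandConfig(tail_fraction=0.05))
    assert len(isl) == 1
    assert isl.iloc[0]["n_significant_snp"] == len(sig) == 50
    assert isl.iloc[0]["start_bp"] == sig[0]
    assert isl.iloc[0]["end_bp"] == sig[-1]


def test_merge_gap_controls_island_splitting():
    """Two clusters 2 Mb apart: two islands at 500 kb merge gap, one at 3 Mb."""
    cluster1 = list(range(1_000_000, 1_200_000, 40_000))
    cluster2 = list(range(3_200_000, 3_400_000, 40_000))
    background = list(range(6_000_000, 8_000_000, 40_000))
    allpos = sorted(cluster1 + cluster2 + background)
    scan = _scan_with_significant(allpos, cluster1 + cluster2)
    snp_map = map_frame([("1", allpos)])
    two = call_islands(scan, snp_map, IslandConfig(tail_fraction=0.05, merge_gap_bp=500_000))
    one = call_islands(scan, snp_map, IslandConfig(tail_fraction=0.05, merge_gap_bp=3_000_000))
    assert len(two) == 2 and len(one) == 1
    assert one.iloc[0]["start_bp"] == cluster1[0] and one.iloc[0]["end_bp"] == cluster2[-1]


def test_no_significant_snps_means_no_islands():
    positions = list(range(10_000, 500_000, 10_000))
    scan = _scan_with_significant(positions, [])
    assert len(call_islands(scan, map_frame([("1", positions)]),
                            IslandConfig(tail_fraction=0.05))) == 0


def island_row(pop, chrom, start, end, nsig=5):
    return dict(population=pop, chrom=str(chrom), start_bp=start, end_bp=end,
                n_significant_snp=nsig, n_total_snp=nsig, min_pct=50.0, max_z=5.0)


def test_identical_islands_in_two_populations_become_one_region():
    isl = pd.DataFrame([island_row("A", 1, 100, 200), island_row("B", 1, 100, 200)])
    regions, members = shared_islands(isl, all_populations=["A", "B"])
    assert len(regions) == 1
    assert regions.iloc[0]["populations"] == "All"
    assert len(members) == 2


def test_chained_overlaps_union_transitively():
    """A overlaps B, B overlaps C, A and C disjoint: one region {A, B, C}."""
    isl = pd.DataFrame([island_row("A", 1, 100, 300),
                        island_row("B", 1, 250, 600),
                        island_row("C", 1, 550, 900)])
    regions, members = shared_islands(isl)
    assert len(regions) == 1
    assert regions.iloc[0]["populations"] == "A, B, C"
    assert regions.iloc[0]["start_bp"] == 100 and regions.iloc[0]["end_bp"] == 900


def test_disjoint_islands_pass_through_and_counts_are_preserved():
    isl = pd.DataFrame([island_row("A", 1, 100, 200),
                        island_row("B", 1, 5_000, 6_000),
                        island_row("A", 2, 100, 200)])
    regions, members = shared_islands(isl)
    assert len(regions) == 3
    # bookkeeping identity: per-population counts sum to total memberships
    per_pop = isl.groupby("population").size().sum()
    assert per_pop == len(members) == regions["n_member_islands"].sum()


def test_invalid_island_config_rejected():
    with pytest.raises(ValueError):
        IslandConfig(tail_fraction=0.5)
    with pytest.raises(ValueError):
        IslandConfig(merge_gap_bp=-1)
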