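import numpy as np
import pandas as pd
import pytest

from rohscan.engine import (CalibrationError, RohCallConfig, RohClassParams,
                            calibrate_class_params, classify_roh, detect_roh,
                            first_pass_roh, scan_consecutive, second_pass_roh)
from rohscan.io import HET, HOM_A1, HOM_A2, MISSING
from rohscan.simulate import SimConfig, simulate_dataset

from _oracles import brute_force_runs
from conftest import make_dataset

o, h, x = HOM_A1, HET, MISSING


def scan(geno, pos=None, **kw):
    geno = np.asarray(geno)
    if pos is None:
        pos = np.arange(1, len(geno) + 1) * 75_000
    defaults = dict(max_het=1, max_missing=1, min_snp=15, min_len_bp=1_000_000,
                    max_gap_bp=100_000)
    defaults.update(kw)
    return scan_consecutive(geno, pos, **defaults)


# ---------------------------------------------------------------------------
# scan_consecutive
# ---------------------------------------------------------------------------

def test_all_heterozygous_yields_nothing():
    assert scan([h] * 30) == []


def test_clean_homozygous_stretch_is_one_run():
    """20 homozygous markers at 75 kb spacing: a single run over all 20."""
    runs = scan([o] * 20)
    assert runs == [(0, 19, 20, 0, 0, 19 * 75_000)]


def test_het_budget_terminates_before_the_violating_call():
    geno = [o] * 40
    geno[10] = h
    geno[25] = h
    runs = scan(geno, min_snp=5, min_len_bp=0)
    assert [(r[0], r[1]) for r in runs] == [(0, 24), (26, 39)]
    assert runs[0][3] == 1 and runs[1][3] == 0
    assert runs == brute_force_runs(geno, np.arange(1, 41) * 75_000, 1, 1, 5, 0, 100_000)


def test_gap_splits_run():
    pos = np.arange(1, 41) * 75_000
    pos[20:] += 150_000  # 225 kb gap between markers 19 and 20
    runs = scan([o] * 40, pos=pos, min_snp=5, min_len_bp=0)
    assert [(r[0], r[1]) for r in runs] == [(0, 19), (20, 39)]


def test_runs_are_trimmed_to_homozygous_ends():
    geno = [h, x] + [o] * 20 + [x, h]
    runs = scan(geno, min_snp=5, min_len_bp=0)
    assert [(r[0], r[1]) for r in runs] == [(2, 21)]
    assert runs[0][3] == 0 and runs[0][4] == 0


def test_unsorted_positions_rejected():
    with pytest.raises(ValueError, match="sorted"):
        scan_consecutive(np.array([o, o, o]), np.array([3, 2, 1]),
                         max_het=1, max_missing=1, min_snp=2, min_len_bp=0,
                         max_gap_bp=100_000)


def test_scan_matches_brute_force_oracle_on_random_chromosomes():
    """Exact equality with the independent window enumerator, 100 replicates."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(5, 201))
        geno = rng.choice([HOM_A1, HOM_A2, HET, MISSING], size=n,
                          p=[0.4, 0.3, 0.22, 0.08])
        pos = np.cumsum(rng.integers(1_000, 160_000, size=n))
        mh = int(rng.integers(0, 4))
        mm = int(rng.integers(0, 3))
        ms = int(rng.choice([2, 5, 15]))
        ml = int(rng.choice([0, 200_000, 1_000_000]))
        got = scan_consecutive(geno, pos, max_het=mh, max_missing=mm,
                               min_snp=ms, min_len_bp=ml, max_gap_bp=100_000)
        want = brute_force_runs(geno, pos, mh, mm, ms, ml, 100_000)
        assert got == want


def test_runs_disjoint_ordered_and_within_allowances():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(30, 150))
        geno = rng.choice([HOM_A1, HET, MISSING], size=n, p=[0.6, 0.3, 0.1])
        pos = np.cumsum(rng.integers(1_000, 90_000, size=n))
        runs = scan_consecutive(geno, pos, max_het=2, max_missing=1,
                                min_snp=3, min_len_bp=0, max_gap_bp=100_000)
        prev_end = -1
        for (s, e, nsnp, nh, nm, ln) in runs:
            assert s > prev_end
            prev_end = e
            assert nh <= 2 and nm <= 1
            assert geno[s] in (HOM_A1, HOM_A2) and geno[e] in (HOM_A1, HOM_A2)


def test_raising_allowances_only_grows_the_feasible_window_set():
    """The set of constraint-satisfying windows is monotone in the allowances
    (total covered bp of the greedy segmentation is not, a property of
    left-greedy scanning)."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = 60
        geno = rng.choice([HOM_A1, HET, MISSING], size=n, p=[0.6, 0.3, 0.1])
        pos = np.cumsum(rng.integers(1_000, 90_000, size=n))

        def windows(mh, mm):
            out = set()
            for i in range(n):
                for j in range(i, n):
                    g = geno[i:j + 1]
                    if geno[i] == HET or geno[i] == MISSING:
                        continue
                    if geno[j] == HET or geno[j] == MISSING:
                        continue
                    if np.any(np.diff(pos[i:j + 1]) > 100_000):
                        continue
                    if (g == HET).sum() <= mh and (g == MISSING).sum() <= mm:
                        out.add((i, j))
            return out

        assert windows(1, 1) <= windows(2, 1) <= windows(2, 2)


def test_determinism_under_sample_reordering():
    cfg = SimConfig(seed=5, n_chromosomes=1, chromosome_length_bp=20_000_000,
                    snp_density_per_mb=100.0, populations=(("P", 6),),
                    tracts_per_class=(("2-4Mb", 1),))
    ds, _ = simulate_dataset(cfg)
    perm = np.random.default_rng(1).permutation(ds.n_samples)
    ds_perm = ds.subset(sample_mask=None)
    ds_perm.samples = ds.samples.iloc[perm].reset_index(drop=True)
    ds_perm.genotypes = ds.genotypes[perm]
    a = first_pass_roh(ds).segments
    b = first_pass_roh(ds_perm).segments
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# classification and calibration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,expected", [
    (1_999_999, "1-2Mb"),
    (2_000_000, "2-4Mb"),
    (7_999_999, "4-8Mb"),
    (16_000_000, ">16Mb"),
    (60_000_000, ">16Mb"),
])
def test_length_class_assignment_half_open(length, expected):
    assert classify_roh(length) == expected


def test_length_below_smallest_class_rejected():
    with pytest.raises(ValueError):
        classify_roh(999_999)


def _pass1_frame(mean_snps):
    rows = []
    labels = RohCallConfig().class_labels
    for lab, m in zip(labels, mean_snps):
        if m is None:
            continue
        rows.append(dict(sample="s", population="p", chrom="1", start_bp=1,
                         end_bp=2, start_idx=0, end_idx=1, n_snp=m, n_het=0,
                         n_missing=0, length_bp=1_500_000, **{"class": lab}))
    from rohscan.engine import SEGMENT_COLUMNS
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def test_calibration_arithmetic():
    """round(420 x 0.0025) = 1 heterozygote, round(420 x 0.0014) = 1 missing."""
    params = calibrate_class_params(_pass1_frame([420, None, None, None, None]))
    row = params.row("1-2Mb")
    assert row["max_het"] == 1 and row["max_missing"] == 1


def test_calibration_reproduces_published_missing_pattern():
    """Class mean SNP counts {420, 840, 1570, 3000, 5600} with the 0.14%
    missing rate give the allowance ladder 1, 1, 2, 4, 8."""
    params = calibrate_class_params(_pass1_frame([420, 840, 1570, 3000, 5600]))
    assert list(params.table["max_missing"]) == [1, 1, 2, 4, 8]
    assert list(params.table["max_het"]) == [1, 2, 4, 8, 14]


def test_zero_error_rate_floors_at_min_allowance():
    cfg0 = RohCallConfig(genotype_error_rate=0.0)
    params = calibrate_class_params(_pass1_frame([420, None, None, None, None]), cfg0)
    assert params.row("1-2Mb")["max_het"] == 1
    cfg_no_floor = RohCallConfig(genotype_error_rate=0.0, min_allowance=0)
    params0 = calibrate_class_params(_pass1_frame([420, None, None, None, None]), cfg_no_floor)
    assert params0.row("1-2Mb")["max_het"] == 0


def test_empty_classes_inherit_nearest_populated():
    with pytest.warns(UserWarning, match="inherit"):
        params = calibrate_class_params(_pass1_frame([None, None, 1570, None, None]))
    assert (params.table["max_het"] == 4).all()
    assert params.table["inherited"].tolist() == [True, True, False, True, True]


def test_all_classes_empty_raises():
    with pytest.raises(CalibrationError):
        calibrate_class_params(_pass1_frame([None] * 5))


@pytest.mark.parametrize("rule,expected", [("nearest", 8), ("floor", 7), ("ceiling", 8)])
def test_rounding_rules(rule, expected):
    cfg = RohCallConfig(rounding=rule)
    params = calibrate_class_params(_pass1_frame([None, None, None, 3000, None]), cfg)
    assert params.row("8-16Mb")["max_het"] == expected  # 3000 x 0.0025 = 7.5


# ---------------------------------------------------------------------------
# two-pass detection on planted data
# ---------------------------------------------------------------------------

def test_no_long_homozygous_stretch_means_empty_pass1():
    """Alternating het/hom at 20 kb spacing: even with the permissive pass-1
    allowances no window reaches the 1 Mb class floor."""
    geno = np.tile([o, h], 200)[None, :]
    ds = make_dataset(geno, positions=np.arange(1, 401) * 20_000)
    assert len(first_pass_roh(ds)) == 0


def test_planted_tracts_recovered_and_classified_without_errors():
    """With zero error/missing rates a 3 Mb and a 10 Mb tract come back as
    one segment each, in classes 2-4 Mb and 8-16 Mb, identically in both
    passes."""
    cfg = SimConfig(seed=21, n_chromosomes=2, chromosome_length_bp=30_000_000,
                    snp_density_per_mb=120.0, populations=(("P", 4),),
                    het_error_rate=0.0, missing_rate=0.0,
                    fixed_tract_lengths_bp=(3_000_000, 10_000_000))
    ds, truth = simulate_dataset(cfg)
    p2, params, p1 = detect_roh(ds)
    for _, t in truth.tracts.iterrows():
        pos = ds.snp_map.loc[ds.snp_map["chrom"] == t["chrom"], "pos"].to_numpy()
        first = pos[np.searchsorted(pos, t["start_bp"])]
        last = pos[np.searchsorted(pos, t["end_bp"], side="right") - 1]
        for rs in (p1, p2):
            seg = rs.segments
            hit = seg[(seg["sample"] == t["sample"]) & (seg["chrom"] == t["chrom"])
                      & (seg["start_bp"] <= first) & (seg["end_bp"] >= last)]
            assert len(hit) == 1, f"tract {t['start_bp']}-{t['end_bp']} not recovered whole"
            assert hit.iloc[0]["class"] == t["class"]


def _params_like_published():
    labels = RohCallConfig().class_labels
    return RohClassParams(pd.DataFrame({
        "class": labels,
        "min_length_bp": [1_000_000, 2_000_000, 4_000_000, 8_000_000, 16_000_000],
        "mean_snp_count": [420.0, 840.0, 1570.0, 3000.0, 5600.0],
        "mean_length_bp": [1.5e6, 3e6, 6e6, 12e6, 20e6],
        "n_runs": [1] * 5,
        "max_het": [1, 2, 4, 7, 12],
        "max_missing": [1, 1, 2, 4, 8],
        "inherited": [False] * 5,
    }))


def test_large_tract_with_ten_errors_recovered_whole():
    """A 20 Mb homozygous stretch carrying 10 heterozygous error calls is one
    >16 Mb segment under the 12-heterozygote allowance, not fragments."""
    n = 600  # 50 kb spacing -> ~30 Mb chromosome
    geno = np.tile([o, h, h], n // 3)  # het-dense background after the tract
    lo, hi = 100, 500  # markers 100..500 span 20 Mb
    geno[:lo] = h  # fully heterozygous lead-in: the run starts at the tract
    geno[lo:hi + 1] = o
    err = np.linspace(lo + 20, hi - 20, 10).astype(int)
    geno[err] = h
    ds = make_dataset(geno[None, :], positions=np.arange(1, n + 1) * 50_000)
    p2 = second_pass_roh(ds, _params_like_published())
    seg = p2.segments
    big = seg[seg["class"] == ">16Mb"]
    assert len(big) == 1
    assert big.iloc[0]["start_idx"] <= lo and big.iloc[0]["end_idx"] >= hi
    assert big.iloc[0]["n_het"] >= 10


def test_small_tract_with_two_errors_rejected():
    """A 1.5 Mb tract with 2 heterozygous calls exceeds the 1-het allowance
    of the 1-2 Mb class and its fragments die on min_snp/min length."""
    geno = np.tile([h, o, h], 40)  # background that blocks run extension
    tract = np.full(30, o)  # 30 markers x 50 kb = 1.45 Mb span
    tract[[10, 20]] = h
    geno = np.concatenate([geno[:60], tract, geno[60:]])
    ds = make_dataset(geno[None, :], positions=np.arange(1, len(geno) + 1) * 50_000)
    p2 = second_pass_roh(ds, _params_like_published())
    assert len(p2) == 0
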