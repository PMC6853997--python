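"""Count summaries, two-group tests, co-labeling and ISH intensity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cordmapper.abundance import (
    colabel_counts,
    compare_counts,
    compare_intensity,
    intensity_quantify,
    summarize_counts,
    IntensityMeasurement,
)
from cordmapper.errors import ConfigError, DataError, DegenerateDataError


# --------------------------------------------------------------- summaries

def _count_df(rows):
    return pd.DataFrame(rows, columns=["embryo_id", "group", "axial_level",
                                       "section_id", "count"])


def test_embryo_mean_over_sections():
    df = _count_df([("A", "control", "thoracic", f"s{i}", 10) for i in range(5)])
    (s,) = summarize_counts(df, unit="embryo")
    assert s.unit_means == {"A": 10.0}
    assert s.mean == 10.0


def test_sem_hand_value():
    """Embryo means {10, 11, 12}: grand mean 11, SEM = sd(1)/sqrt(3)."""
    rows = [(e, "control", "thoracic", f"{e}s", c)
            for e, c in [("A", 10), ("B", 11), ("C", 12)]]
    (s,) = summarize_counts(_count_df(rows), unit="embryo")
    assert s.mean == pytest.approx(11.0)
    assert s.sem == pytest.approx(1 / np.sqrt(3), abs=1e-4)
    assert s.sem == pytest.approx(0.5774, abs=1e-4)


def test_single_embryo_sem_zero_flagged():
    (s,) = summarize_counts(
        _count_df([("A", "control", "thoracic", "s1", 7)]), unit="embryo")
    assert s.sem == 0.0
    assert s.single_unit_flag


def test_summary_permutation_invariant():
    rows = [("A", "control", "thoracic", "s1", 10),
            ("B", "control", "thoracic", "s2", 14),
            ("A", "control", "thoracic", "s3", 12)]
    s1 = summarize_counts(_count_df(rows))
    s2 = summarize_counts(_count_df(rows[::-1]))
    assert s1[0].mean == s2[0].mean and s1[0].sem == s2[0].sem


# ------------------------------------------------------------------ tests

def test_student_t_hand_computation():
    """a = {10,12,11}, b = {20,22,21}: pooled sd 1, t = -12.247, df = 4."""
    res = compare_counts([10, 12, 11], [20, 22, 21], method="student_t")
    assert res.statistic == pytest.approx(-12.247, abs=1e-3)
    assert res.p_value == pytest.approx(2.552e-4, rel=1e-3)
    assert res.significant


def test_mann_whitney_exact_enumeration():
    """a = {1,2,3}, b = {4,5,6}: U = 0; exhaustive enumeration over all
    C(6,3) = 20 rank splits gives two-sided p = 2/20 = 0.1."""
    res = compare_counts([1, 2, 3], [4, 5, 6], method="mann_whitney")
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    # independent oracle: count splits with U at least as extreme
    pooled = [1, 2, 3, 4, 5, 6]
    extreme = total = 0
    for idx in itertools.combinations(range(6), 3):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(6) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y)
        u = min(u, 9 - u)  # two-sided: distance from either tail
        total += 1
        if u <= 0:
            extreme += 1
    assert res.p_value == pytest.approx(extreme / total)


def test_identical_groups_mann_whitney_p_one():
    res = compare_counts([5, 5, 5], [5, 5, 5], method="mann_whitney")
    assert res.p_value == 1.0
    assert not res.significant


def test_all_identical_t_undefined():
    with pytest.raises(DegenerateDataError):
        compare_counts([5, 5, 5], [5, 5, 5], method="student_t")


def test_symmetry_under_group_swap():
    a, b = [10.0, 12, 11, 13], [20.0, 18, 22, 19]
    r1 = compare_counts(a, b, method="student_t")
    r2 = compare_counts(b, a, method="student_t")
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
    assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
    u1 = compare_counts(a, b, method="mann_whitney")
    u2 = compare_counts(b, a, method="mann_whitney")
    assert u1.p_value == pytest.approx(u2.p_value, rel=1e-12)
    assert u1.statistic + u2.statistic == pytest.approx(len(a) * len(b))


def test_auto_rule_prefers_t_on_clean_normal_data():
    rng = np.random.default_rng(0)
    a = rng.normal(10, 1, 8)
    b = rng.normal(12, 1, 8)
    assert compare_counts(a, b, method="auto").test_used == "student_t"


def test_auto_rule_falls_back_on_skewed_data():
    rng = np.random.default_rng(1)
    a = rng.lognormal(0, 1.5, 20)
    b = rng.lognormal(0.5, 1.5, 20)
    assert compare_counts(a, b, method="auto").test_used == "mann_whitney"


def test_auto_null_rejection_rate_bounded():
    """Pretest cascade keeps the null rejection rate near nominal 0.05."""
    root = np.random.SeedSequence(77)
    rej = 0
    n_reps = 2000
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        a = rng.normal(10, 2, 5)
        b = rng.normal(10, 2, 5)
        if compare_counts(a, b, method="auto").p_value <= 0.05:
            rej += 1
    assert rej / n_reps <= 0.07


def test_threshold_behavior_exact():
    res = compare_counts([1, 2, 3], [4, 5, 6], method="mann_whitney",
                         threshold=0.1)
    assert res.significant  # p = 0.1 <= 0.1 counts as significant
    res2 = compare_counts([1, 2, 3], [4, 5, 6], method="mann_whitney",
                          threshold=0.09)
    assert not res2.significant


# ------------------------------------------------------------- co-labeling

def _cells(section, n_total, n_colabel):
    rows = []
    for i in range(n_total):
        markers = "Foxd3;Pou2f2" if i < n_colabel else "Foxd3"
        rows.append({"cell_id": f"{section}c{i}", "section_id": section,
                     "markers": markers})
    return rows


def test_colabel_direct_ratio():
    df = pd.DataFrame(_cells("s1", 10, 4))
    out = colabel_counts(df, {"Pou2f2"}, {"Foxd3"})
    assert out.loc[0, "proportion"] == pytest.approx(0.4)
    assert out.loc[0, "n_reference"] == 10


def test_colabel_required_equals_reference():
    df = pd.DataFrame(_cells("s1", 6, 0))
    out = colabel_counts(df, {"Foxd3"}, {"Foxd3"})
    assert out.loc[0, "proportion"] == 1.0


def test_colabel_zero_denominator_undefined():
    df = pd.DataFrame([{"cell_id": "c1", "section_id": "s1", "markers": "Isl1"}])
    out = colabel_counts(df, {"Pou2f2"}, {"Foxd3"})
    assert np.isnan(out.loc[0, "proportion"])


def test_colabel_recovers_generating_probability():
    """Binomial oracle: with co-label probability 0.3 the pooled
    proportion concentrates near 0.3."""
    from cordmapper import preset_truth, simulate_dataset
    truth = preset_truth("dI3_default", colabel_probs={"Pou2f2": 0.3},
                         cells_per_section=120)
    ds = simulate_dataset(truth, n_embryos=3, sections_per_level=5, seed=5)
    out = colabel_counts(ds["cells"], {"Pou2f2"}, {"Isl1"})
    pooled = out["n_colabeled"].sum() / out["n_reference"].sum()
    assert pooled == pytest.approx(0.3, abs=0.02)


# --------------------------------------------------------------- intensity

def test_uniform_image_zero_net():
    img = np.full((200, 300), 100.0)
    m = intensity_quantify(img, (10, 145, 10, 110), (10, 145, 150, 250),
                           expected_area=13_500)
    assert m.net == 0.0


def test_constructed_signal_block():
    img = np.full((200, 300), 50.0)
    img[10:145, 10:110] = 150.0
    m = intensity_quantify(img, (10, 145, 10, 110), (10, 145, 150, 250),
                           expected_area=13_500)
    assert m.net == pytest.approx(100.0)
    assert m.roi_area_px == 13_500


def test_roi_out_of_bounds_errors():
    img = np.zeros((100, 100))
    with pytest.raises(DataError):
        intensity_quantify(img, (0, 135, 0, 100), (0, 50, 0, 50),
                           expected_area=13_500)


def test_roi_area_mismatch_errors():
    img = np.zeros((200, 300))
    with pytest.raises(ConfigError):
        intensity_quantify(img, (0, 50, 0, 50), (0, 50, 100, 150),
                           expected_area=13_500)


def test_overlapping_background_roi_errors():
    img = np.zeros((200, 300))
    with pytest.raises(ConfigError):
        intensity_quantify(img, (10, 145, 10, 110), (100, 160, 50, 150),
                           expected_area=13_500)


@given(offset=st.floats(-1000, 1000))
def test_net_invariant_to_constant_offset(offset):
    rng = np.random.default_rng(21)
    img = rng.uniform(0, 100, size=(200, 300))
    args = ((10, 145, 10, 110), (10, 145, 150, 250))
    m0 = intensity_quantify(img, *args, expected_area=13_500)
    m1 = intensity_quantify(img + offset, *args, expected_area=13_500)
    assert m1.net == pytest.approx(m0.net, abs=1e-9)


def _measurements(nets_by_embryo, group):
    out = []
    for embryo, nets in nets_by_embryo.items():
        for i, net in enumerate(nets):
            out.append(IntensityMeasurement(
                roi_mean=net, background_mean=0.0, roi_area_px=13_500,
                embryo_id=embryo, group=group, section_id=f"{embryo}s{i}"))
    return out


def test_compare_intensity_identical_groups():
    a = _measurements({"A": [10, 11], "B": [12, 13], "C": [9, 10]}, "control")
    res = compare_intensity(a, a)
    assert res.p_value == pytest.approx(1.0)
    assert res.fold_change == pytest.approx(1.0)


def test_compare_intensity_fold_change_undefined_for_zero_mean():
    a = _measurements({"A": [1, -1], "B": [2, -2]}, "control")
    b = _measurements({"A": [10, 11], "B": [12, 13]}, "mutant")
    res = compare_intensity(a, b)
    assert not res.fold_change_defined
    assert res.fold_change is None
    assert np.isfinite(res.statistic)


def test_compare_intensity_recovers_threefold_change():
    """Generator truth: fold 3.0 at 10% noise, 3 embryos x 5 sections."""
    from cordmapper import preset_truth, simulate_intensity_image
    truth = preset_truth("dI2_default", noise_sd=6.0)  # 10% of amplitude 60
    groups = {}
    root = np.random.SeedSequence(99)
    seeds = iter(root.spawn(30))
    for group, fold in (("control", 1.0), ("mutant", 3.0)):
        ms = []
        for e in range(3):
            for s in range(5):
                sim = simulate_intensity_image(
                    truth, condition_fold=fold,
                    seed=int(next(seeds).generate_state(1)[0] % 2**31))
                m = intensity_quantify(sim["image"], sim["roi"],
                                       sim["background_roi"],
                                       expected_area=13_500,
                                       embryo_id=f"{group}E{e}", group=group)
                ms.append(m)
        groups[group] = ms
    res = compare_intensity(groups["control"], groups["mutant"])
    assert res.fold_change == pytest.approx(3.0, abs=0.3)
    assert res.significant
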