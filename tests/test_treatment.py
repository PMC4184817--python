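"""Treatment statistics against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spinafi.treatment import (
    GroupComparison,
    TreatmentTimecourse,
    before_after_test,
    cohort_to_long,
    long_to_cohort,
    group_anova,
    palpation_contrast,
    relative_response,
    timecourse_regression,
)
from spinafi.roi import AfiResponse, AreaResult, RoiSpec
from spinafi.dff import PhaseSegmentation


def fake_response(intensity_pct, area_px):
    area = AreaResult(area_px, area_px, 0, 0.0, 0.0, 0.0, 0.25, (0, 1))
    seg = PhaseSegmentation((0, 1), None, 0, None, False, 0.0)
    return AfiResponse(intensity_pct, area, seg, False, RoiSpec((10, 10), 4), 16, 0.0, 1.0)


def make_tc(animal, group, values, area=np.nan, times=None):
    times = np.arange(0.0, 5.0 * len(values), 5.0) if times is None else np.asarray(times)
    return TreatmentTimecourse(animal, group, times, np.asarray(values, float), area)


# ---------------------------------------------------------------------------
# Relative responses
# ---------------------------------------------------------------------------


def test_relative_response_identity_and_zero():
    before = fake_response(0.5, 100)
    assert relative_response(before, before).intensity_pct_of_before == pytest.approx(100.0)
    zero = fake_response(0.0, 0)
    rel = relative_response(before, zero)
    assert rel.intensity_pct_of_before == pytest.approx(0.0)
    assert rel.area_pct_of_before == pytest.approx(0.0)


def test_relative_response_ratio():
    rel = relative_response(fake_response(0.50, 200), fake_response(0.30, 50))
    assert rel.intensity_pct_of_before == pytest.approx(60.0)
    assert rel.area_pct_of_before == pytest.approx(25.0)


def test_relative_response_zero_baseline_flagged_undefined():
    with pytest.warns(UserWarning):
        rel = relative_response(fake_response(0.0, 0), fake_response(0.3, 10))
    assert not rel.intensity_defined and not rel.area_defined
    assert np.isnan(rel.intensity_pct_of_before) and np.isnan(rel.area_pct_of_before)


# ---------------------------------------------------------------------------
# Time-course regression
# ---------------------------------------------------------------------------


def test_regression_exact_line():
    tc = make_tc("a", "SCS", [40.0, 70.0, 100.0], times=[0.0, 30.0, 60.0])
    reg = timecourse_regression([tc])
    assert reg.slope == pytest.approx(1.0, abs=1e-12)
    assert reg.pearson_r == pytest.approx(1.0, abs=1e-12)


def test_regression_constant_response_convention():
    tc = make_tc("a", "SCS", [80.0] * 13)
    reg = timecourse_regression([tc])
    assert reg.slope == 0.0 and reg.p_value == 1.0


def test_regression_matches_normal_equations(rng):
    cohort = [
        make_tc(f"a{i}", "SCS", 50 + 0.5 * np.arange(0, 65, 5) + rng.normal(0, 20, 13))
        for i in range(5)
    ]
    reg = timecourse_regression(cohort)
    # independent normal-equations oracle on the per-timepoint means
    t = np.arange(0.0, 65.0, 5.0)
    y = np.mean([tc.relative_intensity_pct for tc in cohort], axis=0)
    sxx = np.sum((t - t.mean()) ** 2)
    sxy = np.sum((t - t.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * t.mean()
    r = sxy / np.sqrt(sxx * np.sum((y - y.mean()) ** 2))
    tstat = r * np.sqrt(len(t) - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(abs(tstat), len(t) - 2)
    assert reg.slope == pytest.approx(slope, abs=1e-10)
    assert reg.intercept == pytest.approx(intercept, abs=1e-10)
    assert reg.pearson_r == pytest.approx(r, abs=1e-10)
    assert reg.p_value == pytest.approx(p, abs=1e-10)
    assert reg.n_points == 13


def test_regression_equivariance(rng):
    cohort = [make_tc(f"a{i}", "sham", rng.normal(100, 10, 13)) for i in range(4)]
    base = timecourse_regression(cohort)
    shifted = [
        make_tc(tc.animal_id, tc.group, tc.relative_intensity_pct + 17.0) for tc in cohort
    ]
    scaled = [
        make_tc(tc.animal_id, tc.group, tc.relative_intensity_pct * 2.5) for tc in cohort
    ]
    assert timecourse_regression(shifted).slope == pytest.approx(base.slope, abs=1e-10)
    assert timecourse_regression(scaled).slope == pytest.approx(2.5 * base.slope, abs=1e-10)


def test_regression_needs_three_timepoints():
    tc = make_tc("a", "SCS", [50.0, 60.0], times=[0.0, 5.0])
    with pytest.raises(ValueError, match="3 distinct timepoints"):
        timecourse_regression([tc])


def test_regression_pooled_mode_uses_all_points(rng):
    cohort = [make_tc(f"a{i}", "SCS", rng.normal(60, 5, 13)) for i in range(3)]
    reg = timecourse_regression(cohort, mode="pooled")
    assert reg.n_points == 39


def test_missing_timepoints_dropped_not_imputed():
    full = make_tc("a", "SCS", [40, 50, 60, 70], times=[0, 5, 10, 15])
    holey = TreatmentTimecourse("b", "SCS", [0, 10, 15], [44, np.nan, 74])
    reg = timecourse_regression([full, holey], t_range=(0, 15))
    # timepoint 5 mean uses only animal a; timepoint 10 only animal a
    assert reg.n_points == 4


# ---------------------------------------------------------------------------
# Before/after paired test
# ---------------------------------------------------------------------------


def test_before_after_all_at_100_is_null():
    cohort = [make_tc(f"a{i}", "sham", [100.0] * 13) for i in range(4)]
    res = before_after_test(cohort)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_before_after_matches_hand_computed_t():
    cohort = [make_tc(a, "SCS", [v] + [0.0] * 12) for a, v in [("a", 60.0), ("b", 70.0), ("c", 80.0)]]
    res = before_after_test(cohort)
    # d = {-40, -30, -20}: mean -30, sd 10 -> t = -30 / (10/sqrt(3))
    t_hand = -30.0 / (10.0 / np.sqrt(3.0))
    p_hand = 2 * stats.t.sf(abs(t_hand), 2)
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)
    assert res.df == (2,)
    assert res.p_value == pytest.approx(p_hand, abs=1e-12)


def test_before_after_needs_two_animals():
    with pytest.raises(ValueError, match="at least 2"):
        before_after_test([make_tc("a", "SCS", [50.0] * 13)])


def test_paired_t_symmetric_on_mirrored_data():
    up = [make_tc(f"a{i}", "SCS", [100.0 + d] + [0.0] * 12) for i, d in enumerate([5, 10, 15])]
    down = [make_tc(f"a{i}", "SCS", [100.0 - d] + [0.0] * 12) for i, d in enumerate([5, 10, 15])]
    r_up, r_down = before_after_test(up), before_after_test(down)
    assert r_up.statistic == pytest.approx(-r_down.statistic, abs=1e-12)
    assert r_up.p_value == pytest.approx(r_down.p_value, abs=1e-12)


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------


def anova_frame(rng, n_per_cell=6, type_effect=0.0, side_effect=0.0, sd=0.1):
    rows = []
    for at, te in (("naive", 0.0), ("neuropathic", type_effect)):
        for side, se in (("ipsilateral", 0.0), ("contralateral", side_effect)):
            for _ in range(n_per_cell):
                rows.append((at, side, 0.5 + te + se + rng.normal(0, sd)))
    return pd.DataFrame(rows, columns=["animal_type", "side", "value"])


def test_balanced_anova_matches_classical_decomposition(rng):
    df = anova_frame(rng, n_per_cell=5, type_effect=0.1, side_effect=-0.05)
    res = group_anova(df)
    y = df["value"].to_numpy()
    grand = y.mean()
    # classical balanced decomposition from cell means
    cells = df.groupby(["animal_type", "side"])["value"].mean()
    a_means = df.groupby("animal_type")["value"].mean()
    b_means = df.groupby("side")["value"].mean()
    n = 5
    ss_a = 2 * n * float(((a_means - grand) ** 2).sum())
    ss_b = 2 * n * float(((b_means - grand) ** 2).sum())
    ss_cells = n * float(((cells - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = float(
        sum(
            (row.value - cells[(row.animal_type, row.side)]) ** 2
            for row in df.itertuples()
        )
    )
    ss_total = float(((y - grand) ** 2).sum())
    assert ss_a + ss_b + ss_ab + ss_res == pytest.approx(ss_total, abs=1e-9)
    ms_res = ss_res / (len(y) - 4)
    f_a = (ss_a / 1) / ms_res
    assert res.statistic == pytest.approx(f_a, abs=1e-8)
    f_b = (ss_b / 1) / ms_res
    assert res.detail["terms"]["C(side)"]["F"] == pytest.approx(f_b, abs=1e-8)


def test_anova_detects_injected_side_effect(rng):
    df = anova_frame(rng, n_per_cell=8, side_effect=0.3, sd=0.1)
    res = group_anova(df)
    assert res.detail["terms"]["C(side)"]["p"] < 0.01


def test_anova_null_calibration():
    rejections = 0
    n_rep = 200
    root = np.random.default_rng(2024)
    for _ in range(n_rep):
        df = anova_frame(root, n_per_cell=5)
        res = group_anova(df)
        rejections += res.p_value < 0.05
    lo, hi = stats.binom.ppf([0.025, 0.975], n_rep, 0.05)
    assert lo <= rejections <= hi


def test_anova_unbalanced_design_runs_with_type_ii(rng):
    df = anova_frame(rng, n_per_cell=7)
    df = df.drop(df[(df.animal_type == "neuropathic")].index[:3])
    res = group_anova(df)
    assert res.detail["ss_type"] == 2
    assert 0 <= res.p_value <= 1


def test_anova_empty_cell_named_in_error(rng):
    df = anova_frame(rng)
    df = df[~((df.animal_type == "naive") & (df.side == "contralateral"))]
    with pytest.raises(ValueError, match="naive.*contralateral"):
        group_anova(df)


def test_anova_single_observation_cell_rejected(rng):
    df = anova_frame(rng, n_per_cell=1)
    with pytest.raises(ValueError, match="single observation"):
        group_anova(df)


# ---------------------------------------------------------------------------
# Palpation contrast
# ---------------------------------------------------------------------------


def test_identical_samples_give_p_one():
    res = palpation_contrast([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_separated_samples_match_welch_oracle():
    naive = [0.0, 0.0, 0.0, 0.0, 0.0]
    neuro = [0.3, 0.4, 0.5, 0.35, 0.45]
    res = palpation_contrast(naive, neuro)
    a, b = np.array(naive), np.array(neuro)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = np.sqrt(va / 5 + vb / 5)
    t_hand = (a.mean() - b.mean()) / se
    df_hand = (va / 5 + vb / 5) ** 2 / ((va / 5) ** 2 / 4 + (vb / 5) ** 2 / 4)
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)
    assert res.df[0] == pytest.approx(df_hand, abs=1e-9)
    assert res.p_value < 0.001


def test_contrast_needs_two_per_group():
    with pytest.raises(ValueError, match="at least 2"):
        palpation_contrast([0.1], [0.2, 0.3])


# ---------------------------------------------------------------------------
# Long-table round trip
# ---------------------------------------------------------------------------


def test_cohort_long_round_trip(rng):
    cohort = [
        make_tc("SCS-01", "SCS", rng.normal(60, 10, 13), area=55.0),
        make_tc("sham-01", "sham", rng.normal(100, 10, 13), area=98.0),
    ]
    back = long_to_cohort(cohort_to_long(cohort))
    assert {tc.animal_id for tc in back} == {"SCS-01", "sham-01"}
    orig = {tc.animal_id: tc for tc in cohort}
    for tc in back:
        np.testing.assert_allclose(
            tc.relative_intensity_pct, orig[tc.animal_id].relative_intensity_pct
        )
        assert tc.relative_area_t0_pct == pytest.approx(orig[tc.animal_id].relative_area_t0_pct)
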