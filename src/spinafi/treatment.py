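"""Treatment time-course and group statistics.

The spinal-cord-stimulation (SCS) experiment expresses each animal's
post-treatment AFI response as a percentage of its before-treatment
response, at T = 0 after 30 min of SCS or sham and then every 5 minutes
up to an hour.  This module implements:

* relative responses (``100 * after / before``),
* the before-vs-T0 paired comparison (one-sample t against 100 %),
* ordinary least squares of the per-timepoint cohort mean against time
  over T = 0..60 min, with Pearson r and the two-sided slope p-value,
* the naïve-vs-neuropathic two-way ANOVA (animal type × side) and the
  palpation unpaired t contrast.

Missing timepoints are dropped, never imputed.  No multiple-testing
correction is applied across the AFI endpoint family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .roi import AfiResponse

__all__ = [
    "TreatmentTimecourse",
    "RegressionResult",
    "GroupComparison",
    "RelativeResponse",
    "relative_response",
    "cohort_to_long",
    "long_to_cohort",
    "timecourse_regression",
    "before_after_test",
    "group_anova",
    "palpation_contrast",
]

BEFORE_TIMEPOINT_MIN = -30.0  # before-treatment recordings precede 30 min of SCS/sham


@dataclass(frozen=True)
class TreatmentTimecourse:
    """Per-animal relative AFI responses after SCS or sham.

    ``timepoints_min`` are minutes relative to cessation of treatment
    (0, 5, ..., 60); the before-treatment recording is coded −30 and is
    100 % by construction.  ``relative_intensity_pct`` may contain NaN
    for failed recordings.  ``relative_area_t0_pct`` is the area of
    excitation at T = 0 as a percentage of the before-treatment area.
    """

    animal_id: str
    group: str
    timepoints_min: np.ndarray
    relative_intensity_pct: np.ndarray
    relative_area_t0_pct: float = np.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints_min", np.asarray(self.timepoints_min, float))
        object.__setattr__(
            self, "relative_intensity_pct", np.asarray(self.relative_intensity_pct, float)
        )
        if self.group not in ("SCS", "sham"):
            raise ValueError("group must be 'SCS' or 'sham'")
        if self.timepoints_min.shape != self.relative_intensity_pct.shape:
            raise ValueError("timepoints and responses must have equal length")
        if np.any(np.diff(self.timepoints_min) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    def value_at(self, t_min: float) -> float:
        idx = np.nonzero(self.timepoints_min == t_min)[0]
        return float(self.relative_intensity_pct[idx[0]]) if idx.size else np.nan


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of relative intensity (%) against time (minutes)."""

    slope: float  # %ΔF/F per minute
    intercept: float
    pearson_r: float
    p_value: float
    n_points: int
    mode: str = "cohort_mean"


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    df: Tuple[float, ...]
    p_value: float
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RelativeResponse:
    intensity_pct_of_before: float
    area_pct_of_before: float
    intensity_defined: bool
    area_defined: bool


def relative_response(
    before: AfiResponse, after: AfiResponse, floor_intensity_pct: float = 1e-3
) -> RelativeResponse:
    """Express a post-treatment response as percent of the pre-treatment one.

    A baseline intensity below ``floor_intensity_pct`` (in %) or a zero
    baseline area makes the corresponding ratio undefined; undefined
    values are NaN-flagged and must be excluded from group means.
    """
    int_ok = abs(before.intensity_pct) >= floor_intensity_pct
    area_ok = before.area.total_pixels > 0
    if not int_ok:
        warnings.warn("before-treatment intensity below floor; relative intensity undefined")
    if not area_ok:
        warnings.warn("before-treatment area is zero; relative area undefined")
    rel_int = 100.0 * after.intensity_pct / before.intensity_pct if int_ok else np.nan
    rel_area = (
        100.0 * after.area.total_pixels / before.area.total_pixels if area_ok else np.nan
    )
    return RelativeResponse(rel_int, rel_area, int_ok, area_ok)


def cohort_to_long(cohort: Sequence[TreatmentTimecourse]) -> pd.DataFrame:
    """Long-format table: animal_id, group, timepoint_min, metric, value."""
    rows = []
    for tc in cohort:
        rows.append((tc.animal_id, tc.group, BEFORE_TIMEPOINT_MIN, "intensity", 100.0))
        for t, v in zip(tc.timepoints_min, tc.relative_intensity_pct):
            rows.append((tc.animal_id, tc.group, float(t), "intensity", float(v)))
        if np.isfinite(tc.relative_area_t0_pct):
            rows.append((tc.animal_id, tc.group, 0.0, "area", float(tc.relative_area_t0_pct)))
    return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint_min", "metric", "value"])


def long_to_cohort(df: pd.DataFrame) -> List[TreatmentTimecourse]:
    """Rebuild per-animal time courses from the long-format table."""
    out: List[TreatmentTimecourse] = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=True):
        inten = sub[(sub["metric"] == "intensity") & (sub["timepoint_min"] >= 0)]
        inten = inten.sort_values("timepoint_min")
        area = sub[(sub["metric"] == "area") & (sub["timepoint_min"] == 0)]
        out.append(
            TreatmentTimecourse(
                animal_id=str(animal),
                group=str(group),
                timepoints_min=inten["timepoint_min"].to_numpy(),
                relative_intensity_pct=inten["value"].to_numpy(),
                relative_area_t0_pct=float(area["value"].iloc[0]) if len(area) else np.nan,
            )
        )
    return out


def timecourse_regression(
    cohort: Sequence[TreatmentTimecourse],
    t_range: Tuple[float, float] = (0.0, 60.0),
    mode: str = "cohort_mean",
) -> RegressionResult:
    """OLS slope of relative AFI intensity against time after treatment.

    ``mode="cohort_mean"`` (default) regresses the per-timepoint mean
    over animals (missing values excluded), matching a fit to the mean
    trajectory; ``mode="pooled"`` regresses all animal × timepoint
    points and is provided for sensitivity analysis.
    """
    if mode not in ("cohort_mean", "pooled"):
        raise ValueError("mode must be 'cohort_mean' or 'pooled'")
    lo, hi = t_range
    xs: list[float] = []
    ys: list[float] = []
    if mode == "cohort_mean":
        times = sorted({float(t) for tc in cohort for t in tc.timepoints_min if lo <= t <= hi})
        for t in times:
            vals = np.array([tc.value_at(t) for tc in cohort])
            vals = vals[np.isfinite(vals)]
            if vals.size:
                xs.append(t)
                ys.append(float(vals.mean()))
    else:
        for tc in cohort:
            for t, v in zip(tc.timepoints_min, tc.relative_intensity_pct):
                if lo <= t <= hi and np.isfinite(v):
                    xs.append(float(t))
                    ys.append(float(v))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct timepoints for the regression")
    if np.allclose(y, y[0]):
        # constant response: slope 0, no association, p = 1 by convention
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(x), mode)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_points=len(x),
        mode=mode,
    )


def before_after_test(
    cohort: Sequence[TreatmentTimecourse], metric: str = "intensity"
) -> GroupComparison:
    """Paired before-vs-T0 comparison.

    Relative values at T = 0 are tested against the before-treatment
    value of 100 % with a two-sided one-sample t-test (equivalent to the
    paired t-test on raw before/after pairs).
    """
    if metric == "intensity":
        vals = np.array([tc.value_at(0.0) for tc in cohort])
    elif metric == "area":
        vals = np.array([tc.relative_area_t0_pct for tc in cohort])
    else:
        raise ValueError("metric must be 'intensity' or 'area'")
    vals = vals[np.isfinite(vals)]
    n = vals.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if np.allclose(vals, 100.0):
        return GroupComparison("paired-t", 0.0, (n - 1,), 1.0, {"n": n, "metric": metric})
    t, p = stats.ttest_1samp(vals, 100.0)
    return GroupComparison(
        "paired-t", float(t), (n - 1,), float(p), {"n": n, "metric": metric, "mean": float(vals.mean())}
    )


def group_anova(df: pd.DataFrame, value: str = "value", ss_type: int = 2) -> GroupComparison:
    """Two-way ANOVA of an AFI endpoint: animal type × side, with interaction.

    Expects columns ``animal_type`` (naive | neuropathic), ``side``
    (ipsilateral | contralateral) and the value column.  Unbalanced
    designs are handled with Type II sums of squares by default; the SS
    type is recorded in the result.  The reported statistic/p belong to
    the ``animal_type`` main effect; all terms are in ``detail``.
    """
    counts = df.groupby(["animal_type", "side"], observed=True)[value].count()
    types = df["animal_type"].unique()
    sides = df["side"].unique()
    for a in types:
        for s in sides:
            if counts.get((a, s), 0) == 0:
                raise ValueError(f"empty design cell: animal_type={a}, side={s}")
    if (counts < 2).any():
        cell = counts[counts < 2].index[0]
        raise ValueError(f"cell {cell} has a single observation: no residual df for interaction")
    model = smf.ols(f"{value} ~ C(animal_type) * C(side)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    terms = {}
    for term in table.index:
        if term == "Residual":
            continue
        terms[term] = {
            "F": float(table.loc[term, "F"]),
            "df": (float(table.loc[term, "df"]), float(table.loc["Residual", "df"])),
            "p": float(table.loc[term, "PR(>F)"]),
        }
    main = terms["C(animal_type)"]
    return GroupComparison(
        "two-way ANOVA",
        main["F"],
        main["df"],
        main["p"],
        {"ss_type": ss_type, "terms": terms},
    )


def palpation_contrast(
    naive: Iterable[float], neuropathic: Iterable[float], welch: bool = True
) -> GroupComparison:
    """Two-sided unpaired t-test of AFI intensities, naïve vs neuropathic.

    Defaults to the Welch (unequal-variance) form; the pooling mode is
    recorded in the result.
    """
    a = np.asarray(list(naive), float)
    b = np.asarray(list(neuropathic), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.allclose(a, a[0]) and np.allclose(b, a[0]):
        return GroupComparison(
            "unpaired-t", 0.0, (a.size + b.size - 2,), 1.0, {"welch": welch}
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else a.size + b.size - 2
    return GroupComparison(
        "unpaired-t",
        float(res.statistic),
        (float(df),),
        float(res.pvalue),
        {"welch": welch, "n": (a.size, b.size)},
    )
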