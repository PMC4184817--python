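"""Behavioral endpoints: von Frey threshold and hotplate latency.

Mechanical sensitivity is probed with von Frey filaments of increasing
force; the withdrawal threshold is the force of the first (lowest)
filament evoking withdrawal on at least three of five applications.
Thermal sensitivity is the latency to hind-paw response on a 51 °C
hotplate, censored at 30 s (animals that do not respond are removed to
prevent tissue injury; a latency of exactly 30 s counts as censored).

Testing happens before nerve ligation (day 0) and at post-operative
days 10, 12 and 14; the day effect is assessed with a one-way
repeated-measures ANOVA followed by Bonferroni-corrected paired
comparisons of day 0 against each later day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .treatment import GroupComparison

__all__ = [
    "DEFAULT_FILAMENTS_G",
    "DAYS",
    "FilamentSeries",
    "BehavioralRecord",
    "vonfrey_threshold",
    "hotplate_latency",
    "rm_anova_days",
    "records_to_wide",
    "records_to_long",
]

# Standard Stoelting rat set (grams); the forces themselves are a
# configurable convention, not a measured quantity.
DEFAULT_FILAMENTS_G: Tuple[float, ...] = (0.4, 0.6, 1.0, 2.0, 4.0, 6.0, 8.0, 15.0, 26.0)
DAYS: Tuple[int, ...] = (0, 10, 12, 14)
HOTPLATE_CUTOFF_S = 30.0
WITHDRAWAL_CRITERION = 3  # of 5 applications


@dataclass(frozen=True)
class FilamentSeries:
    forces_g: Tuple[float, ...] = DEFAULT_FILAMENTS_G

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.forces_g)
        object.__setattr__(self, "forces_g", f)
        if any(x <= 0 for x in f):
            raise ValueError("filament forces must be positive")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("filament forces must be strictly increasing")


@dataclass(frozen=True)
class BehavioralRecord:
    """One animal × day behavioral observation."""

    animal_id: str
    day: int
    vf_threshold_g: float
    vf_censored_high: bool
    hp_latency_s: float
    hp_censored: bool
    group: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.hp_latency_s <= HOTPLATE_CUTOFF_S:
            raise ValueError("hotplate latency must lie in (0, 30] s")
        if self.hp_censored and self.hp_latency_s != HOTPLATE_CUTOFF_S:
            raise ValueError("censored hotplate latency must equal the 30 s cutoff")


def vonfrey_threshold(
    withdrawal_counts: Sequence[int],
    filaments: FilamentSeries = FilamentSeries(),
) -> Tuple[float, bool]:
    """Withdrawal threshold under the 3-of-5 rule.

    ``withdrawal_counts`` holds withdrawals out of five applications per
    filament, in ascending filament order.  Returns the force of the
    first filament reaching >= 3 withdrawals; if none does, the maximum
    force with a censored-high flag.
    """
    counts = list(withdrawal_counts)
    if len(counts) != len(filaments.forces_g):
        raise ValueError("one withdrawal count per filament required")
    for c in counts:
        if not 0 <= int(c) <= 5 or int(c) != c:
            raise ValueError("withdrawal counts must be integers in 0..5")
    for force, c in zip(filaments.forces_g, counts):
        if c >= WITHDRAWAL_CRITERION:
            return force, False
    return filaments.forces_g[-1], True


def hotplate_latency(raw_latency_s: float) -> Tuple[float, bool]:
    """Censor a raw hotplate latency at the 30 s cutoff.

    Latencies of 30 s or more are recorded as 30 s, censored (the animal
    did not respond within the window).
    """
    if raw_latency_s <= 0:
        raise ValueError("latency must be positive")
    if raw_latency_s >= HOTPLATE_CUTOFF_S:
        return HOTPLATE_CUTOFF_S, True
    return float(raw_latency_s), False


def _endpoint_column(endpoint: str) -> str:
    if endpoint in ("vonfrey", "vf", "vf_threshold_g"):
        return "vf_threshold_g"
    if endpoint in ("hotplate", "hp", "hp_latency_s"):
        return "hp_latency_s"
    raise ValueError("endpoint must be 'vonfrey' or 'hotplate'")


def rm_anova_days(
    records: Sequence[BehavioralRecord],
    endpoint: str,
    days: Sequence[int] = DAYS,
    greenhouse_geisser: bool = False,
) -> GroupComparison:
    """One-way repeated-measures ANOVA across testing days.

    Complete cases only: animals missing any day are dropped with a
    warning recorded in the result detail.  Pairwise paired t-tests of
    day 0 versus each later day follow, Bonferroni-corrected by the
    number of comparisons.  The Greenhouse–Geisser option adjusts the
    F-test degrees of freedom for sphericity violations (off by
    default; the flag is recorded).
    """
    col = _endpoint_column(endpoint)
    df = records_to_long(records)
    df = df[df["day"].isin(days)]
    counts = df.groupby("animal_id")["day"].nunique()
    complete = counts[counts == len(days)].index
    dropped = sorted(set(counts.index) - set(complete))
    df = df[df["animal_id"].isin(complete)]
    n = df["animal_id"].nunique()
    if n < 2:
        raise ValueError("need at least 2 animals observed at every day")

    wide_vals = df.pivot(index="animal_id", columns="day", values=col).to_numpy()
    if np.ptp(wide_vals - wide_vals.mean(axis=1, keepdims=True)) == 0:
        # no within-subject variation at all: F = 0, p = 1 by convention
        F, df1, df2 = 0.0, float(len(days) - 1), float((n - 1) * (len(days) - 1))
        p, eps = 1.0, 1.0
    else:
        res = AnovaRM(df, depvar=col, subject="animal_id", within=["day"]).fit()
        row = res.anova_table.iloc[0]
        F = float(row["F Value"])
        df1, df2 = float(row["Num DF"]), float(row["Den DF"])
        if greenhouse_geisser:
            eps = _gg_epsilon(wide_vals)
            p = float(stats.f.sf(F, df1 * eps, df2 * eps))
        else:
            eps = 1.0
            p = float(row["Pr > F"])

    # Bonferroni pairwise comparisons vs day 0
    wide = df.pivot(index="animal_id", columns="day", values=col)
    later = [d for d in days if d != days[0]]
    m = len(later)
    pairwise = {}
    for d in later:
        t, praw = stats.ttest_rel(wide[days[0]], wide[d])
        if np.isnan(t):  # identical columns
            t, praw = 0.0, 1.0
        pairwise[d] = {
            "t": float(t),
            "df": n - 1,
            "p_raw": float(praw),
            "p_bonferroni": float(min(1.0, praw * m)),
        }
    return GroupComparison(
        "repeated-measures ANOVA",
        F,
        (df1 * eps, df2 * eps),
        p,
        {
            "endpoint": col,
            "n_animals": n,
            "dropped_incomplete": dropped,
            "greenhouse_geisser": greenhouse_geisser,
            "epsilon": eps,
            "pairwise_vs_day0": pairwise,
        },
    )


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the within-subject covariance."""
    S = np.cov(data, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    return float(num / den) if den > 0 else 1.0


def records_to_long(records: Sequence[BehavioralRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "day": [r.day for r in records],
            "vf_threshold_g": [r.vf_threshold_g for r in records],
            "vf_censored_high": [r.vf_censored_high for r in records],
            "hp_latency_s": [r.hp_latency_s for r in records],
            "hp_censored": [r.hp_censored for r in records],
        }
    )


def records_to_wide(records: Sequence[BehavioralRecord]) -> pd.DataFrame:
    """Wide per-animal table: VF0..VF14, HP0..HP14 (grams and seconds)."""
    long = records_to_long(records)
    out = {}
    for animal, sub in long.groupby("animal_id"):
        row = {"animal_id": animal, "group": sub["group"].iloc[0]}
        for _, r in sub.iterrows():
            row[f"VF{int(r['day'])}"] = r["vf_threshold_g"]
            row[f"HP{int(r['day'])}"] = r["hp_latency_s"]
        out[animal] = row
    cols = ["animal_id", "group"] + [f"VF{d}" for d in DAYS] + [f"HP{d}" for d in DAYS]
    df = pd.DataFrame(list(out.values()))
    return df.reindex(columns=[c for c in cols if c in df.columns])
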