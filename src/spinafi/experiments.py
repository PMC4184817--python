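"""End-to-end drivers for the two experiments.

Experiment 1 — sensitization: AFI responses to noxious electrical
stimulation in naïve versus neuropathic animals (two-way ANOVA of
intensity and area: animal type × side) and to innocuous palpation
(unpaired t contrast of ipsilateral intensities, the allodynia test).

Experiment 2 — treatment: relative AFI responses after SCS or sham
(paired before-vs-T0 tests for intensity and area; OLS regression of
the mean relative intensity against time over T = 0..60 min per arm).

Both run entirely from the synthetic generator (or from CSV input for
experiment 2) and write CSV + text reports whose every number is
traceable to a table cell.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dff import compute_dff
from .io import RunConfig, responses_to_frame
from .roi import AfiResponse, RoiSpec, measure_response
from .simulate import (
    COHORT_PRESETS,
    MOVIE_PRESETS,
    MoviePreset,
    SceneParams,
    generate_scs_cohort,
    render_movie,
)
from .treatment import (
    GroupComparison,
    RegressionResult,
    TreatmentTimecourse,
    before_after_test,
    group_anova,
    palpation_contrast,
    timecourse_regression,
)

logger = logging.getLogger("spinafi")

DEFAULT_ARMS: Dict[str, Tuple[str, int]] = {
    # arm -> (movie preset, number of animals)
    "naive-noxious": ("noxious-naive", 20),
    "neuropathic-noxious": ("noxious-neuropathic", 13),
    "naive-palpation": ("palpation-naive", 5),
    "neuropathic-palpation": ("palpation-neuropathic", 5),
}


@dataclass(frozen=True)
class Experiment1Report:
    responses: pd.DataFrame
    anova_intensity: GroupComparison
    anova_area: GroupComparison
    palpation: GroupComparison
    qc: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Experiment2Report:
    long_table: pd.DataFrame
    before_after: Dict[str, Dict[str, GroupComparison]]
    regression: Dict[str, RegressionResult]
    qc: dict = field(default_factory=dict)


def _measure_both_sides(
    dff, scene: SceneParams, config: RunConfig
) -> Tuple[AfiResponse, AfiResponse]:
    geo = scene.derived_geometry()
    size = config.roi_size or scene.default_roi_size()
    ipsi = RoiSpec(center=geo["center_ipsi"], size=size, side="ipsilateral")
    contra = RoiSpec(center=geo["center_contra"], size=size, side="contralateral")
    kw = dict(threshold_pct=config.threshold_pct, band_k=config.band_k, area_mode=config.area_mode)
    return measure_response(dff, ipsi, **kw), measure_response(dff, contra, **kw)


def simulate_arm_responses(
    arm: str,
    preset: MoviePreset | str,
    n: int,
    scene: SceneParams,
    config: RunConfig,
    seed_seq: np.random.SeedSequence,
) -> List[Tuple[str, AfiResponse]]:
    """Render and measure one experimental arm, one movie per animal."""
    if isinstance(preset, str):
        preset = MOVIE_PRESETS[preset]
    out: List[Tuple[str, AfiResponse]] = []
    children = seed_seq.spawn(n)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        scale = (
            float(rng.lognormal(0.0, preset.amp_cv)),
            float(rng.lognormal(0.0, preset.amp_cv)),
        )
        movie_seed = int(child.generate_state(1, np.uint32)[0])
        stack, _ = render_movie(scene, preset, seed=movie_seed, amp_scale=scale)
        dff = compute_dff(stack, config.baseline_window)
        rec = f"{arm}-{i + 1:02d}"
        for resp in _measure_both_sides(dff, scene, config):
            out.append((rec, resp))
    return out


def run_experiment_1(
    config: RunConfig,
    scene: Optional[SceneParams] = None,
    arms: Optional[Dict[str, Tuple[str, int]]] = None,
) -> Experiment1Report:
    """Sensitization experiment on generated recordings.

    ``arms`` maps arm name -> (movie preset name, n animals); all four
    default arms must be present.
    """
    scene = scene or SceneParams()
    arms = arms if arms is not None else dict(DEFAULT_ARMS)
    for required in DEFAULT_ARMS:
        if required not in arms:
            raise ValueError(f"missing experimental arm: {required}")
    seed_seq = np.random.SeedSequence(config.seed)
    arm_seqs = dict(zip(sorted(arms), seed_seq.spawn(len(arms))))

    responses: List[Tuple[str, AfiResponse]] = []
    arm_of: Dict[str, str] = {}
    for arm, (preset, n) in arms.items():
        rs = simulate_arm_responses(arm, preset, n, scene, config, arm_seqs[arm])
        responses.extend(rs)
        for rec_id, _ in rs:
            arm_of[rec_id] = arm
    table = responses_to_frame(responses)
    table["arm"] = table["recording_id"].map(arm_of)
    table["animal_type"] = np.where(table["arm"].str.startswith("naive"), "naive", "neuropathic")
    table["stimulus"] = np.where(
        table["arm"].str.endswith("noxious"), "noxious", "palpation"
    )

    nox = table[table["stimulus"] == "noxious"]
    anova_int = group_anova(
        nox.rename(columns={"intensity_pct": "value"}), ss_type=config.ss_type
    )
    anova_area = group_anova(
        nox.rename(columns={"area_pixels": "value"}).astype({"value": float}),
        ss_type=config.ss_type,
    )
    palp = table[(table["stimulus"] == "palpation") & (table["side"] == "ipsilateral")]
    contrast = palpation_contrast(
        palp.loc[palp["animal_type"] == "naive", "intensity_pct"],
        palp.loc[palp["animal_type"] == "neuropathic", "intensity_pct"],
        welch=config.welch,
    )
    qc = {
        "n_no_response": int(table["no_response"].sum()),
        "n_recordings": int(table["recording_id"].nunique()),
    }
    return Experiment1Report(table, anova_int, anova_area, contrast, qc)


def run_experiment_2(
    config: RunConfig,
    cohort: Optional[Sequence[TreatmentTimecourse]] = None,
    n_scs: int = 7,
    n_sham: int = 6,
    scs_preset: str = "scs",
    sham_preset: str = "sham",
    t_range: Tuple[float, float] = (0.0, 60.0),
    regression_mode: str = "cohort_mean",
) -> Experiment2Report:
    """Treatment experiment on a provided or generated cohort."""
    if cohort is None:
        cohort = generate_scs_cohort(
            n_scs=n_scs,
            n_sham=n_sham,
            scs_preset=scs_preset,
            sham_preset=sham_preset,
            seed=config.seed,
        )
    from .treatment import cohort_to_long

    arms = sorted({tc.group for tc in cohort})
    before_after: Dict[str, Dict[str, GroupComparison]] = {}
    regression: Dict[str, RegressionResult] = {}
    for arm in arms:
        members = [tc for tc in cohort if tc.group == arm]
        before_after[arm] = {
            "intensity": before_after_test(members, "intensity"),
            "area": before_after_test(members, "area"),
        }
        regression[arm] = timecourse_regression(members, t_range, regression_mode)
        logger.info(
            "arm %s: slope %.3f %%/min (p=%.3g, r=%.3f, n=%d)",
            arm,
            regression[arm].slope,
            regression[arm].p_value,
            regression[arm].pearson_r,
            regression[arm].n_points,
        )
    qc = {"n_animals": {arm: sum(tc.group == arm for tc in cohort) for arm in arms}}
    return Experiment2Report(cohort_to_long(list(cohort)), before_after, regression, qc)


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------


def _comparison_rows(name: str, c: GroupComparison) -> List[dict]:
    rows = [
        {
            "analysis": name,
            "test": c.test,
            "term": "main",
            "statistic": c.statistic,
            "df": "/".join(f"{d:g}" for d in c.df),
            "p_value": c.p_value,
        }
    ]
    for term, t in c.detail.get("terms", {}).items():
        rows.append(
            {
                "analysis": name,
                "test": c.test,
                "term": term,
                "statistic": t["F"],
                "df": "/".join(f"{d:g}" for d in t["df"]),
                "p_value": t["p"],
            }
        )
    return rows


def write_manifest(config: RunConfig, outdir: Path, extra: Optional[dict] = None) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    path = outdir / "run_manifest.yaml"
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def write_experiment1_report(report: Experiment1Report, config: RunConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.responses.to_csv(outdir / "responses.csv", index=False)
    stats_rows = (
        _comparison_rows("anova_intensity", report.anova_intensity)
        + _comparison_rows("anova_area", report.anova_area)
        + _comparison_rows("palpation_contrast_ipsi", report.palpation)
    )
    pd.DataFrame(stats_rows).to_csv(outdir / "stats.csv", index=False)
    lines = ["Experiment 1: sensitization", ""]
    for name, c in (
        ("Two-way ANOVA, AFI intensity (animal type x side)", report.anova_intensity),
        ("Two-way ANOVA, area of excitation (animal type x side)", report.anova_area),
        ("Unpaired t, palpation ipsilateral intensity (naive vs neuropathic)", report.palpation),
    ):
        lines.append(f"{name}:")
        lines.append(
            f"  {c.test}: statistic={c.statistic:.4g}, df={c.df}, p={c.p_value:.4g}"
        )
        for term, t in c.detail.get("terms", {}).items():
            lines.append(f"    {term}: F={t['F']:.4g}, df={t['df']}, p={t['p']:.4g}")
    lines.append("")
    lines.append(f"QC: {report.qc}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    write_manifest(config, outdir, {"experiment": 1})
    return outdir


def write_experiment2_report(report: Experiment2Report, config: RunConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.long_table.to_csv(outdir / "timecourse.csv", index=False)
    rows = []
    for arm, reg in report.regression.items():
        rows.append(
            {
                "analysis": f"regression_{arm}",
                "test": "OLS",
                "term": "slope",
                "statistic": reg.slope,
                "df": reg.n_points - 2,
                "p_value": reg.p_value,
                "pearson_r": reg.pearson_r,
                "intercept": reg.intercept,
            }
        )
    for arm, tests in report.before_after.items():
        for metric, c in tests.items():
            rows.append(
                {
                    "analysis": f"before_after_{arm}_{metric}",
                    "test": c.test,
                    "term": "T0 vs 100%",
                    "statistic": c.statistic,
                    "df": c.df[0],
                    "p_value": c.p_value,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "stats.csv", index=False)
    lines = ["Experiment 2: SCS vs sham treatment", ""]
    for arm, reg in report.regression.items():
        lines.append(
            f"{arm}: slope {reg.slope:.2f} %dF/F per min, r={reg.pearson_r:.3f}, "
            f"p={reg.p_value:.3g} (n={reg.n_points} timepoints, {reg.mode})"
        )
    for arm, tests in report.before_after.items():
        for metric, c in tests.items():
            lines.append(
                f"{arm} before vs T=0 ({metric}): t={c.statistic:.3f}, "
                f"df={c.df[0]:g}, p={c.p_value:.3g}"
            )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    write_manifest(config, outdir, {"experiment": 2})
    return outdir
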