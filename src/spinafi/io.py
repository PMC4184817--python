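"""File formats and run configuration.

Movies travel as multi-page TIFF (16-bit grayscale in, 32-bit float
ΔF/F out) with a YAML sidecar carrying the time base, stimulus epoch,
pixel size and orientation.  Tables are UTF-8 CSV with a header row:
per-ROI traces (time_s, dff), per-recording response reports, the
long-format treatment table (animal_id, group, timepoint_min, metric,
value) and the wide behavioral table (VF0..VF14, HP0..HP14).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .dff import DffStack, FluorescenceStack
from .roi import AfiResponse
from .treatment import TreatmentTimecourse, cohort_to_long, long_to_cohort

__all__ = [
    "RunConfig",
    "load_config",
    "write_stack",
    "read_stack",
    "write_dff_stack",
    "write_roi_trace",
    "responses_to_frame",
    "write_responses",
    "write_timecourse_csv",
    "read_timecourse_csv",
]


@dataclass(frozen=True)
class RunConfig:
    """Options of one analysis run, echoed verbatim into the run manifest."""

    output_dir: str = "."
    seed: int = 0
    baseline_window: Optional[Tuple[int, int]] = None
    threshold_pct: float = 0.25
    band_k: float = 2.0
    roi_size: Optional[int] = None
    rois: Tuple[Tuple[int, int], ...] = ()
    pixel_size_um: float = 10.0
    orientation: str = "left-top"
    ss_type: int = 2
    welch: bool = True
    greenhouse_geisser: bool = False
    area_mode: str = "max"

    def __post_init__(self) -> None:
        if self.threshold_pct <= 0:
            raise ValueError("threshold_pct must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "rois" in raw:
        raw["rois"] = tuple(tuple(r) for r in raw["rois"])
    if raw.get("baseline_window") is not None:
        raw["baseline_window"] = tuple(raw["baseline_window"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# TIFF stacks + YAML sidecars
# ---------------------------------------------------------------------------


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".yaml")


def write_stack(
    stack: FluorescenceStack, path: str | Path, extra_sidecar: Optional[dict] = None
) -> Path:
    """Write a raw stack as multi-page TIFF plus a YAML sidecar."""
    path = Path(path)
    frames = stack.frames
    if np.issubdtype(frames.dtype, np.integer):
        data = frames.astype(np.uint16)
    else:
        data = frames.astype(np.float32)
    tifffile.imwrite(path, data)
    meta = {
        "frame_times_s": [float(t) for t in stack.frame_times],
        "stim_onset_s": float(stack.stim_onset),
        "stim_offset_s": float(stack.stim_offset),
        "pixel_size_um": float(stack.pixel_size_um),
        "orientation": stack.orientation,
    }
    if extra_sidecar:
        meta["ground_truth"] = extra_sidecar
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_stack(path: str | Path, sidecar: Optional[str | Path] = None) -> FluorescenceStack:
    """Read a multi-page TIFF plus its sidecar into a FluorescenceStack.

    The sidecar must provide either ``frame_times_s`` or a fixed
    ``frame_interval_s`` together with the stimulus epoch.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    with open(sidecar, "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    if "frame_times_s" in meta:
        times = np.asarray(meta["frame_times_s"], float)
    elif "frame_interval_s" in meta:
        times = np.arange(frames.shape[0]) * float(meta["frame_interval_s"])
    else:
        raise ValueError("sidecar must carry frame_times_s or frame_interval_s")
    return FluorescenceStack(
        frames=frames,
        frame_times=times,
        stim_onset=float(meta["stim_onset_s"]),
        stim_offset=float(meta["stim_offset_s"]),
        pixel_size_um=float(meta.get("pixel_size_um", 10.0)),
        orientation=meta.get("orientation", "left-top"),
    )


def write_dff_stack(dff: DffStack, path: str | Path) -> Path:
    """Write the ΔF/F stack as 32-bit float TIFF (sidecar carries the rest)."""
    path = Path(path)
    tifffile.imwrite(path, dff.dff.astype(np.float32))
    meta = {
        "frame_times_s": [float(t) for t in dff.frame_times],
        "stim_onset_s": float(dff.stim_onset),
        "stim_offset_s": float(dff.stim_offset),
        "baseline_window": [int(b) for b in dff.baseline_window],
        "pixel_size_um": float(dff.pixel_size_um),
        "orientation": dff.orientation,
        "n_invalid_pixels": int((~dff.valid).sum()),
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def write_roi_trace(times_s: np.ndarray, trace: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": times_s, "dff": trace}).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Response reports
# ---------------------------------------------------------------------------

RESPONSE_COLUMNS = [
    "recording_id",
    "side",
    "roi_center_row",
    "roi_center_col",
    "intensity_pct",
    "area_pixels",
    "area_mm2",
    "threshold_pct",
    "no_response",
    "light_phase_start_s",
    "light_phase_end_s",
]


def responses_to_frame(responses: Sequence[Tuple[str, AfiResponse]]) -> pd.DataFrame:
    rows = []
    for rec_id, r in responses:
        rows.append(
            {
                "recording_id": rec_id,
                "side": r.roi.side,
                "roi_center_row": r.roi.center[0],
                "roi_center_col": r.roi.center[1],
                "intensity_pct": r.intensity_pct,
                "area_pixels": r.area.total_pixels,
                "area_mm2": r.area.total_mm2,
                "threshold_pct": r.area.threshold_pct,
                "no_response": r.no_response,
                "light_phase_start_s": r.light_phase_start_s,
                "light_phase_end_s": r.light_phase_end_s,
            }
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def write_responses(responses: Sequence[Tuple[str, AfiResponse]], path: str | Path) -> Path:
    path = Path(path)
    responses_to_frame(responses).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Treatment time-course tables
# ---------------------------------------------------------------------------

TIMECOURSE_COLUMNS = ["animal_id", "group", "timepoint_min", "metric", "value"]


def write_timecourse_csv(cohort: Sequence[TreatmentTimecourse], path: str | Path) -> Path:
    path = Path(path)
    cohort_to_long(cohort).to_csv(path, index=False)
    return path


def read_timecourse_csv(path: str | Path) -> List[TreatmentTimecourse]:
    """Read and validate the long-format treatment table.

    Malformed rows are rejected with their 1-based file line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["metric"] not in ("intensity", "area"):
            raise ValueError(f"{path}: line {line}: unknown metric {row['metric']!r}")
        if row["group"] not in ("SCS", "sham"):
            raise ValueError(f"{path}: line {line}: unknown group {row['group']!r}")
        for col in ("timepoint_min", "value"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {line}: non-numeric {col} {row[col]!r}"
                ) from None
    df["timepoint_min"] = df["timepoint_min"].astype(float)
    df["value"] = df["value"].astype(float)
    return long_to_cohort(df)
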