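"""ROI metrics: AFI intensity and area of excitation.

Two scalar outcomes summarize one recording, per cord side:

* **AFI intensity** — the maximal ΔF/F of the light phase of the
  ROI-mean trace (reported in percent).
* **Area of excitation** — the number of valid pixels whose maximal
  ΔF/F over an analysis window (default: the light phase) strictly
  exceeds a predefined ΔF/F level that is kept constant across
  recordings.  Reported in pixels and mm².

ROIs are square selections (default 20×20 pixels, the acquisition-scale
convention); the ipsi/contra split is the horizontal image midline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .dff import DffStack, PhaseSegmentation, segment_phases

__all__ = [
    "RoiSpec",
    "RoiTrace",
    "AreaResult",
    "AfiResponse",
    "roi_trace",
    "afi_intensity",
    "area_of_excitation",
    "measure_response",
]


@dataclass(frozen=True)
class RoiSpec:
    """A square region of interest.

    ``center`` is (row, col); the square spans ``size`` pixels per edge,
    rows ``center[0] - size//2`` up to (exclusive) that plus ``size``.
    """

    center: Tuple[int, int]
    size: int = 20
    side: str = "ipsilateral"
    spinal_level: str = ""

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ROI size must be >= 1")
        if self.side not in ("ipsilateral", "contralateral"):
            raise ValueError("side must be 'ipsilateral' or 'contralateral'")

    def bounds(self) -> Tuple[int, int, int, int]:
        r0 = self.center[0] - self.size // 2
        c0 = self.center[1] - self.size // 2
        return r0, r0 + self.size, c0, c0 + self.size

    def validate_within(self, shape: Tuple[int, int]) -> None:
        r0, r1, c0, c1 = self.bounds()
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValueError(
                f"ROI {self.center} size {self.size} exceeds image bounds {shape}"
            )


class RoiTrace(NamedTuple):
    trace: np.ndarray
    n_valid_pixels: int


@dataclass(frozen=True)
class AreaResult:
    """Supra-threshold pixel counts, total and split at the midline."""

    total_pixels: int
    ipsi_pixels: int
    contra_pixels: int
    total_mm2: float
    ipsi_mm2: float
    contra_mm2: float
    threshold_pct: float
    window: Tuple[int, int]


@dataclass(frozen=True)
class AfiResponse:
    """Scalar metrics of one recording for one ROI."""

    intensity_pct: float
    area: AreaResult
    segmentation: PhaseSegmentation
    no_response: bool
    roi: RoiSpec
    n_valid_pixels: int
    light_phase_start_s: Optional[float]
    light_phase_end_s: Optional[float]


def _px_to_mm2(n_px: int, pixel_size_um: float) -> float:
    return n_px * (pixel_size_um / 1000.0) ** 2


def roi_trace(dff: DffStack, roi: RoiSpec) -> RoiTrace:
    """Per-frame mean ΔF/F over the valid pixels of an ROI.

    Masked (invalid) pixels are excluded from the mean; the count of
    valid pixels is returned alongside the trace.
    """
    roi.validate_within(dff.shape)
    r0, r1, c0, c1 = roi.bounds()
    sub_valid = dff.valid[r0:r1, c0:c1]
    n_valid = int(sub_valid.sum())
    if n_valid == 0:
        raise ValueError("ROI has no valid pixels")
    sub = dff.dff[:, r0:r1, c0:c1]
    trace = sub[:, sub_valid].mean(axis=1)
    return RoiTrace(trace=trace, n_valid_pixels=n_valid)


def afi_intensity(
    dff: DffStack,
    roi: RoiSpec,
    band_k: float = 2.0,
    segmentation: Optional[PhaseSegmentation] = None,
) -> Tuple[float, PhaseSegmentation]:
    """AFI intensity: maximal light-phase ΔF/F of the ROI-mean trace, in %.

    When no light phase is detected the maximum is taken over all
    post-onset frames and the segmentation's no-response flag is set.
    """
    tr = roi_trace(dff, roi)
    if segmentation is None:
        segmentation = segment_phases(tr.trace, dff.frame_times, dff.stim_onset, band_k)
    if segmentation.light_phase is not None:
        lo, hi = segmentation.light_phase
        value = float(np.max(tr.trace[lo:hi]))
    else:
        value = float(tr.trace[segmentation.peak_frame])
    return 100.0 * value, segmentation


def area_of_excitation(
    dff: DffStack,
    threshold_pct: float,
    window: Optional[Tuple[int, int]] = None,
    segmentation: Optional[PhaseSegmentation] = None,
    midline_row: Optional[int] = None,
    mode: str = "max",
) -> AreaResult:
    """Count pixels whose ΔF/F exceeds a fixed level over a frame window.

    Membership uses each valid pixel's maximum ΔF/F over the window
    (``mode="max"``, the default, matching an intensity defined as a
    maximum) or its mean (``mode="mean"``).  The comparison is strict: a
    pixel whose statistic equals the threshold exactly is not counted.

    ``window`` defaults to the light phase of ``segmentation``; one of
    the two must be provided.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive (percent ΔF/F)")
    if window is None:
        if segmentation is None or segmentation.light_phase is None:
            raise ValueError("window empty: provide a frame window or a segmentation with a light phase")
        window = segmentation.light_phase
    w0, w1 = int(window[0]), int(window[1])
    if w1 <= w0 or w0 < 0 or w1 > dff.n_frames:
        raise ValueError("window empty or out of range")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")

    stat = dff.dff[w0:w1].max(axis=0) if mode == "max" else dff.dff[w0:w1].mean(axis=0)
    supra = (stat > threshold_pct / 100.0) & dff.valid

    mid = dff.midline_row if midline_row is None else int(midline_row)
    ipsi_lo, ipsi_hi = (0, mid) if dff.orientation == "left-top" else (mid, dff.shape[0])
    ipsi_mask = np.zeros(dff.shape, dtype=bool)
    ipsi_mask[ipsi_lo:ipsi_hi] = True

    total = int(supra.sum())
    ipsi = int((supra & ipsi_mask).sum())
    contra = total - ipsi
    px = dff.pixel_size_um
    return AreaResult(
        total_pixels=total,
        ipsi_pixels=ipsi,
        contra_pixels=contra,
        total_mm2=_px_to_mm2(total, px),
        ipsi_mm2=_px_to_mm2(ipsi, px),
        contra_mm2=_px_to_mm2(contra, px),
        threshold_pct=float(threshold_pct),
        window=(w0, w1),
    )


def measure_response(
    dff: DffStack,
    roi: RoiSpec,
    threshold_pct: float = 0.25,
    band_k: float = 2.0,
    area_mode: str = "max",
) -> AfiResponse:
    """Full per-recording ROI measurement: intensity, area, phase timing.

    With a no-response segmentation the intensity comes from the global
    post-onset maximum (flagged) and the area window falls back to all
    post-onset frames; the area may then legitimately be 0.
    """
    tr = roi_trace(dff, roi)
    seg = segment_phases(tr.trace, dff.frame_times, dff.stim_onset, band_k)
    intensity, _ = afi_intensity(dff, roi, band_k=band_k, segmentation=seg)
    if seg.light_phase is not None:
        window = seg.light_phase
        t0 = float(dff.frame_times[seg.light_phase[0]])
        t1_idx = min(seg.light_phase[1], dff.n_frames - 1)
        t1 = float(dff.frame_times[t1_idx])
    else:
        first_post = int(np.sum(dff.frame_times < dff.stim_onset))
        window = (first_post, dff.n_frames)
        t0 = t1 = None
    area = area_of_excitation(dff, threshold_pct, window=window, mode=area_mode)
    return AfiResponse(
        intensity_pct=intensity,
        area=area,
        segmentation=seg,
        no_response=seg.no_response,
        roi=roi,
        n_valid_pixels=tr.n_valid_pixels,
        light_phase_start_s=t0,
        light_phase_end_s=t1,
    )
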