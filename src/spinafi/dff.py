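"""Fractional fluorescence change (ΔF/F) and biphasic-phase segmentation.

Widefield flavoprotein autofluorescence responses are quantified as the
change of each pixel's fluorescence relative to its mean over frames
preceding the stimulus (the baseline window):

    dff[t, r, c] = (F[t, r, c] - F0[r, c]) / F0[r, c]

with ``F0`` the per-pixel baseline mean.  The evoked response is biphasic:
a positive deflection (light phase, the oxidation of mitochondrial
flavoproteins) followed by a sub-baseline deflection (dark phase, the
subsequent reduction).  Only the light phase is used as the default
activity measure.

ΔF/F is stored unitless throughout the package and rendered as percent
only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "FluorescenceStack",
    "DffStack",
    "PhaseSegmentation",
    "compute_dff",
    "segment_phases",
]

_UINT16_MAX = 65535


@dataclass(frozen=True)
class FluorescenceStack:
    """A raw fluorescence movie plus its time base and stimulus epoch.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative counts within 16-bit range.
        Floats are accepted (idealized noiseless renders); acquisition
        data is integer.
    frame_times
        Seconds from recording start, strictly increasing, length ``T``.
    stim_onset, stim_offset
        Stimulus epoch in seconds; at least two frames must lie strictly
        before ``stim_onset`` so a baseline exists.
    pixel_size_um
        Micrometers per pixel edge.
    orientation
        Which image half holds the left (ipsilateral) cord side;
        ``"left-top"`` (default, matching the acquisition convention that
        the upper half is left) or ``"left-bottom"``.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    stim_onset: float
    stim_offset: float
    pixel_size_um: float = 10.0
    orientation: str = "left-top"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", times)
        if frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if times.shape != (frames.shape[0],):
            raise ValueError("frame_times must match the time axis length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if frames.size and (frames.min() < 0 or frames.max() > _UINT16_MAX):
            raise ValueError("counts must lie within the 16-bit range [0, 65535]")
        if not self.stim_onset < self.stim_offset:
            raise ValueError("stim_onset must precede stim_offset")
        if int(np.sum(times < self.stim_onset)) < 2:
            raise ValueError(
                "need at least 2 frames strictly before stim_onset (empty baseline)"
            )
        if self.orientation not in ("left-top", "left-bottom"):
            raise ValueError("orientation must be 'left-top' or 'left-bottom'")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def pre_stimulus_window(self) -> Tuple[int, int]:
        """Half-open frame range covering every frame strictly before onset."""
        return 0, int(np.sum(self.frame_times < self.stim_onset))


@dataclass(frozen=True)
class DffStack:
    """Per-pixel fractional fluorescence change relative to baseline.

    ``valid`` marks pixels with a positive baseline mean; dead pixels and
    structures such as the dural vein (baseline 0) are masked, never
    interpolated, and excluded from every downstream metric.
    """

    dff: np.ndarray
    f0: np.ndarray
    valid: np.ndarray
    baseline_window: Tuple[int, int]
    frame_times: np.ndarray
    stim_onset: float
    stim_offset: float
    pixel_size_um: float = 10.0
    orientation: str = "left-top"

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.dff.shape[1], self.dff.shape[2]

    @property
    def midline_row(self) -> int:
        return self.dff.shape[1] // 2

    def ipsilateral_rows(self) -> Tuple[int, int]:
        """Half-open row range of the ipsilateral (left) cord side."""
        if self.orientation == "left-top":
            return 0, self.midline_row
        return self.midline_row, self.dff.shape[1]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Light/dark phase frame ranges of a biphasic ΔF/F trace.

    Frame ranges are half-open ``[start, stop)`` indices into the trace.
    ``dark_phase`` is ``None`` when the trace never drops below the noise
    band after the light phase.  ``no_response`` is set when the trace
    never exceeds the band post-onset; ``peak_frame`` then falls back to
    the global post-onset argmax so a (flagged) intensity can still be
    reported.
    """

    light_phase: Optional[Tuple[int, int]]
    dark_phase: Optional[Tuple[int, int]]
    peak_frame: int
    trough_frame: Optional[int]
    no_response: bool
    band: float
    band_k: float = 2.0


def compute_dff(
    stack: FluorescenceStack,
    baseline_window: Optional[Tuple[int, int]] = None,
    smooth_sigma_px: Optional[float] = None,
) -> DffStack:
    """Convert a raw stack into a ΔF/F stack.

    Parameters
    ----------
    stack
        Input movie.
    baseline_window
        Half-open frame range used as baseline.  Defaults to every frame
        strictly before stimulus onset.  Must be non-empty and lie
        entirely before onset.
    smooth_sigma_px
        Optional per-frame spatial Gaussian smoothing (pixels) applied to
        the ΔF/F stack; off by default.

    Returns
    -------
    DffStack
        ``dff`` has per-pixel mean 0 over the baseline window by
        construction; pixels with baseline mean 0 are flagged invalid and
        carry ΔF/F 0.
    """
    if baseline_window is None:
        baseline_window = stack.pre_stimulus_window()
    b0, b1 = int(baseline_window[0]), int(baseline_window[1])
    if b1 <= b0 or b0 < 0 or b1 > stack.n_frames:
        raise ValueError("no pre-stimulus frames: baseline window is empty or out of range")
    if stack.frame_times[b1 - 1] >= stack.stim_onset:
        raise ValueError("baseline window overlaps the stimulus")

    frames = np.asarray(stack.frames, dtype=np.float64)
    f0 = frames[b0:b1].mean(axis=0)
    valid = f0 > 0
    denom = np.where(valid, f0, 1.0)
    dff = (frames - f0) / denom
    dff[:, ~valid] = 0.0
    if smooth_sigma_px is not None and smooth_sigma_px > 0:
        for t in range(dff.shape[0]):
            dff[t] = ndimage.gaussian_filter(dff[t], smooth_sigma_px)
    return DffStack(
        dff=dff,
        f0=f0,
        valid=valid,
        baseline_window=(b0, b1),
        frame_times=stack.frame_times,
        stim_onset=stack.stim_onset,
        stim_offset=stack.stim_offset,
        pixel_size_um=stack.pixel_size_um,
        orientation=stack.orientation,
    )


def _runs(mask: np.ndarray) -> list[Tuple[int, int]]:
    """Half-open index ranges of contiguous True runs."""
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def segment_phases(
    trace: np.ndarray,
    frame_times: np.ndarray,
    stim_onset: float,
    band_k: float = 2.0,
) -> PhaseSegmentation:
    """Segment a ΔF/F trace into light and dark phases.

    The noise band is ``band_k`` times the standard deviation of the
    pre-onset samples.  The light phase is the maximal (longest; earliest
    on ties) contiguous post-onset run with ``trace > band``; the dark
    phase is the first contiguous run after the light phase with
    ``trace < -band``.  A trace that never exceeds the band yields a
    no-response segmentation (flag, not an exception).
    """
    trace = np.asarray(trace, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if trace.shape != frame_times.shape:
        raise ValueError("trace and frame_times must have equal length")
    pre = frame_times < stim_onset
    if pre.sum() < 2 or pre.all():
        raise ValueError("trace must cover pre- and post-onset frames")
    sd = float(np.std(trace[pre], ddof=1))
    band = band_k * sd

    first_post = int(np.argmax(~pre))
    post = trace[first_post:]
    above = _runs(post > band)
    if not above:
        peak = first_post + int(np.argmax(post))
        return PhaseSegmentation(None, None, peak, None, True, band, band_k)

    # longest run; ties broken by earliest start
    s, e = max(above, key=lambda r: (r[1] - r[0], -r[0]))
    light = (first_post + s, first_post + e)
    peak = light[0] + int(np.argmax(trace[light[0] : light[1]]))

    dark = None
    trough = None
    tail = trace[light[1] :]
    below = _runs(tail < -band)
    if below:
        ds, de = below[0]
        dark = (light[1] + ds, light[1] + de)
        trough = dark[0] + int(np.argmin(trace[dark[0] : dark[1]]))
    return PhaseSegmentation(light, dark, peak, trough, False, band, band_k)
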