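"""Synthetic AFI recordings, treatment cohorts and behavioral tables.

Everything the pipeline consumes can be generated here with known ground
truth: movies carrying a spatially localized biphasic fluorescence
transient over shot noise, bleaching and a dural-vein artifact; SCS/sham
cohort time courses with a configured suppression and linear recovery;
and behavioral tables with a configurable neuropathy effect.

All generators are pure functions of (parameters, seed).

Amplitudes and kernel time constants are illustrative — chosen to sit
inside the ±0.75 % ΔF/F display range typical of spinal AFI and to give
a light phase spanning roughly a 10 s stimulus — except the two cohort
recovery slopes (0.92 and 0.19 %ΔF/F·min⁻¹ for SCS and sham), which are
the experiment's reported mean-trajectory slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .behavior import (
    DAYS,
    BehavioralRecord,
    FilamentSeries,
    hotplate_latency,
    vonfrey_threshold,
)
from .dff import FluorescenceStack
from .treatment import TreatmentTimecourse

__all__ = [
    "SceneParams",
    "MoviePreset",
    "CohortPreset",
    "BehaviorPreset",
    "MOVIE_PRESETS",
    "COHORT_PRESETS",
    "biphasic_kernel",
    "kernel_shape",
    "spatial_profile",
    "render_movie",
    "generate_scs_cohort",
    "generate_behavior_cohort",
    "behavior_records",
]

_UINT16_MAX = 65535


# ---------------------------------------------------------------------------
# Scene geometry and movie rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics and noise of one synthetic recording.

    Defaults describe the test-scale scene: a 64×64 field (the
    acquisition-scale equivalent is 512×512), 10 frames/s for 40 s with
    a 10 s stimulus starting at t = 5 s, baseline 50000 counts, Gaussian
    shot noise with SD ``noise_scale * sqrt(counts)`` (Poisson
    approximation; the scale models camera gain), and a 3-row dural-vein
    band at the midline rendered at a constant low level (0 → masked by
    the ΔF/F stage).  Blob geometry is derived from the image size
    unless overridden: flat-top (plateau + Gaussian shoulder) profiles
    centered mid-way down each cord half.
    """

    shape: Tuple[int, int] = (64, 64)
    pixel_size_um: float = 10.0
    frame_rate_hz: float = 10.0
    duration_s: float = 40.0
    stim_onset_s: float = 5.0
    stim_duration_s: float = 10.0
    stim_rate_hz: float = 10.0
    # biphasic kernel
    tau_rise_s: float = 1.0
    tau_decay_s: float = 6.0
    undershoot: float = 0.6
    tau_undershoot_s: float = 10.0
    # photometry
    baseline_counts: float = 50000.0
    noise_scale: float = 0.5
    bleach_per_s: float = 0.0
    # artifacts
    vein_rows: int = 3
    vein_level: float = 0.0
    # blob geometry (None -> derived from shape)
    blob_center_ipsi: Optional[Tuple[int, int]] = None
    blob_center_contra: Optional[Tuple[int, int]] = None
    plateau_radius_px: Optional[float] = None
    shoulder_sigma_px: Optional[float] = None
    orientation: str = "left-top"

    @property
    def stim_offset_s(self) -> float:
        return self.stim_onset_s + self.stim_duration_s

    def frame_times(self) -> np.ndarray:
        n = int(round(self.duration_s * self.frame_rate_hz))
        return np.arange(n) / self.frame_rate_hz

    def derived_geometry(self) -> Dict[str, object]:
        h, w = self.shape
        return {
            "center_ipsi": self.blob_center_ipsi or (h // 4, w // 2),
            "center_contra": self.blob_center_contra or (3 * h // 4, w // 2),
            "plateau": self.plateau_radius_px if self.plateau_radius_px is not None else h / 8.0,
            "sigma": self.shoulder_sigma_px if self.shoulder_sigma_px is not None else h / 16.0,
        }

    def default_roi_size(self) -> int:
        """ROI edge that fits inside the blob plateau at this scale."""
        g = self.derived_geometry()
        return max(2, int(g["plateau"] * math.sqrt(2)) - 1)

    def vein_row_range(self) -> Tuple[int, int]:
        mid = self.shape[0] // 2
        lo = mid - self.vein_rows // 2
        return lo, lo + self.vein_rows


@dataclass(frozen=True)
class MoviePreset:
    """Side-specific peak ΔF/F amplitudes for one experimental condition."""

    name: str
    amp_ipsi: float
    amp_contra: float
    amp_cv: float = 0.2  # between-animal lognormal scatter of amplitudes

    def __post_init__(self) -> None:
        for a in (self.amp_ipsi, self.amp_contra):
            if not -0.0075 < a < 0.0075:
                raise ValueError("amplitudes must stay within the ±0.75% display range")


MOVIE_PRESETS: Dict[str, MoviePreset] = {
    # Noxious electrical stimulation drives both cord halves; nerve injury
    # does not change the (near-saturating) response.
    "noxious-naive": MoviePreset("noxious-naive", 0.005, 0.002),
    "noxious-neuropathic": MoviePreset("noxious-neuropathic", 0.005, 0.002),
    # Innocuous palpation: no response in naive animals, an ipsilateral
    # response after nerve injury (allodynia).
    "palpation-naive": MoviePreset("palpation-naive", 0.0, 0.0),
    "palpation-neuropathic": MoviePreset("palpation-neuropathic", 0.003, 0.0),
    "null": MoviePreset("null", 0.0, 0.0),
}


def biphasic_kernel(
    t: np.ndarray | float,
    a: float = 1.0,
    tau_rise_s: float = 1.0,
    tau_decay_s: float = 6.0,
    undershoot: float = 0.6,
    tau_undershoot_s: float = 10.0,
) -> np.ndarray:
    """Closed-form biphasic response kernel.

    ``k(t) = a * [(1 - exp(-t/τ1)) * exp(-t/τ2)
                  - u * (1 - exp(-t/τ2)) * exp(-t/τ3)]``

    for t ≥ 0 (0 before), with a single positive peak followed, for
    ``u > 0``, by a single sub-baseline trough; ``k(0) = 0``.
    """
    if min(tau_rise_s, tau_decay_s, tau_undershoot_s) <= 0:
        raise ValueError("time constants must be positive")
    if not 0 <= undershoot < 1:
        raise ValueError("undershoot fraction must lie in [0, 1)")
    t = np.asarray(t, dtype=float)
    pos = (1.0 - np.exp(-t / tau_rise_s)) * np.exp(-t / tau_decay_s)
    neg = undershoot * (1.0 - np.exp(-t / tau_decay_s)) * np.exp(-t / tau_undershoot_s)
    out = a * (pos - neg)
    return np.where(t >= 0, out, 0.0)


def kernel_shape(scene: SceneParams, times_from_onset: np.ndarray) -> np.ndarray:
    """Kernel time course normalized to unit peak over the given frames.

    The rendered peak ΔF/F therefore equals the amplitude parameter
    exactly — the package's amplitude convention.
    """
    k = biphasic_kernel(
        times_from_onset,
        1.0,
        scene.tau_rise_s,
        scene.tau_decay_s,
        scene.undershoot,
        scene.tau_undershoot_s,
    )
    peak = k.max()
    return k / peak if peak > 0 else k


def spatial_profile(
    shape: Tuple[int, int], center: Tuple[int, int], plateau: float, sigma: float
) -> np.ndarray:
    """Flat-top Gaussian: 1 inside ``plateau``, Gaussian shoulder outside."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    excess = np.clip(d - plateau, 0.0, None)
    return np.exp(-(excess**2) / (2.0 * sigma**2))


def supra_threshold_radius(scene: SceneParams, amp: float, threshold: float) -> float:
    """Analytic radius of the contour where the peak ΔF/F equals the threshold."""
    g = scene.derived_geometry()
    if amp <= threshold:
        return 0.0
    return g["plateau"] + g["sigma"] * math.sqrt(2.0 * math.log(amp / threshold))


def render_movie(
    scene: SceneParams,
    preset: MoviePreset | str = "noxious-neuropathic",
    seed: int = 0,
    amp_scale: Tuple[float, float] = (1.0, 1.0),
    quantize: Optional[bool] = None,
) -> Tuple[FluorescenceStack, Dict[str, object]]:
    """Render one synthetic recording and its ground-truth sidecar.

    ``frames = round(B * (1 - bleach*t) * (1 + k(t) * G(r, c)) + noise)``
    with ``G`` the summed per-side flat-top profiles scaled by the
    preset amplitudes, and noise Gaussian with SD
    ``noise_scale * sqrt(signal)``.  Vein-band pixels are set to a
    constant low level.  Frames are clipped to 16-bit and the clipped
    fraction reported.  ``quantize`` defaults to True when noise is on;
    noiseless renders stay floating-point so they expose the exact
    ground truth.
    """
    if isinstance(preset, str):
        preset = MOVIE_PRESETS[preset]
    amp_ipsi = preset.amp_ipsi * amp_scale[0]
    amp_contra = preset.amp_contra * amp_scale[1]

    geo = scene.derived_geometry()
    times = scene.frame_times()
    if times.size < 4 or (times < scene.stim_onset_s).sum() < 2:
        raise ValueError("scene too short: need at least 2 pre-stimulus frames")

    max_amp = max(abs(amp_ipsi), abs(amp_contra))
    headroom = scene.baseline_counts * (1 + max_amp) + 6 * scene.noise_scale * math.sqrt(
        max(scene.baseline_counts, 1.0)
    )
    if headroom > _UINT16_MAX:
        raise ValueError(
            f"expected dynamic range {headroom:.0f} counts exceeds 16-bit headroom"
        )

    k = kernel_shape(scene, times - scene.stim_onset_s)
    field2d = amp_ipsi * spatial_profile(
        scene.shape, geo["center_ipsi"], geo["plateau"], geo["sigma"]
    ) + amp_contra * spatial_profile(
        scene.shape, geo["center_contra"], geo["plateau"], geo["sigma"]
    )
    bleach = 1.0 - scene.bleach_per_s * times
    signal = (
        scene.baseline_counts
        * bleach[:, None, None]
        * (1.0 + k[:, None, None] * field2d[None, :, :])
    )

    rng = np.random.default_rng(seed)
    if scene.noise_scale > 0:
        noise = rng.standard_normal(signal.shape) * (
            scene.noise_scale * np.sqrt(np.clip(signal, 0.0, None))
        )
        frames = signal + noise
    else:
        frames = signal
    v0, v1 = scene.vein_row_range()
    if v1 > v0:
        frames[:, v0:v1, :] = scene.vein_level

    if quantize is None:
        quantize = scene.noise_scale > 0
    clipped = float(np.mean((frames < 0) | (frames > _UINT16_MAX)))
    frames = np.clip(frames, 0.0, _UINT16_MAX)
    if quantize:
        frames = np.round(frames).astype(np.uint16)

    stack = FluorescenceStack(
        frames=frames,
        frame_times=times,
        stim_onset=scene.stim_onset_s,
        stim_offset=scene.stim_offset_s,
        pixel_size_um=scene.pixel_size_um,
        orientation=scene.orientation,
    )
    sidecar: Dict[str, object] = {
        "seed": int(seed),
        "preset": preset.name,
        "amp_ipsi": amp_ipsi,
        "amp_contra": amp_contra,
        "center_ipsi": tuple(int(x) for x in geo["center_ipsi"]),
        "center_contra": tuple(int(x) for x in geo["center_contra"]),
        "plateau_radius_px": float(geo["plateau"]),
        "shoulder_sigma_px": float(geo["sigma"]),
        "kernel": {
            "tau_rise_s": scene.tau_rise_s,
            "tau_decay_s": scene.tau_decay_s,
            "undershoot": scene.undershoot,
            "tau_undershoot_s": scene.tau_undershoot_s,
        },
        "baseline_counts": scene.baseline_counts,
        "noise_scale": scene.noise_scale,
        "bleach_per_s": scene.bleach_per_s,
        "vein_row_range": list(scene.vein_row_range()),
        "vein_level": scene.vein_level,
        "clipped_fraction": clipped,
        "quantized": bool(quantize),
        "stim_rate_hz": scene.stim_rate_hz,
    }
    return stack, sidecar


# ---------------------------------------------------------------------------
# Treatment cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortPreset:
    """Relative-response model for one treatment arm.

    ``relative(t) = s0 + slope*t + animal_effect + noise`` at each
    timepoint (percent of before-treatment), with animal effects
    N(0, sd_between) and i.i.d. within-recording noise N(0, sd_within).
    The relative area at T = 0 is ``area_s0 + N(0, area_sd)``.
    """

    name: str
    s0_pct: float
    slope_pct_per_min: float
    sd_between: float
    sd_within: float
    area_s0_pct: float
    area_sd: float


COHORT_PRESETS: Dict[str, CohortPreset] = {
    # SCS: strong suppression directly after treatment, linear loss of
    # efficacy at 0.92 %/min (the reported SCS mean-trajectory slope).
    "scs": CohortPreset("scs", 45.0, 0.92, 10.0, 35.0, 40.0, 50.0),
    # Sham: no suppression; the nominal 0.19 %/min drift is dominated by
    # recording noise and statistically indistinguishable from zero.
    "sham": CohortPreset("sham", 100.0, 0.19, 10.0, 60.0, 100.0, 25.0),
    # Exact null for calibration runs.
    "null": CohortPreset("null", 100.0, 0.0, 10.0, 60.0, 100.0, 25.0),
}

DEFAULT_TIMEPOINTS_MIN = tuple(float(t) for t in range(0, 65, 5))


def _simulate_arm(
    n: int,
    group: str,
    preset: CohortPreset,
    timepoints: Sequence[float],
    rng: np.random.Generator,
) -> List[TreatmentTimecourse]:
    t = np.asarray(timepoints, float)
    out = []
    for i in range(n):
        animal = rng.normal(0.0, preset.sd_between) if preset.sd_between > 0 else 0.0
        noise = (
            rng.normal(0.0, preset.sd_within, size=t.size)
            if preset.sd_within > 0
            else np.zeros(t.size)
        )
        rel = preset.s0_pct + preset.slope_pct_per_min * t + animal + noise
        area = preset.area_s0_pct + (
            rng.normal(0.0, preset.area_sd) if preset.area_sd > 0 else 0.0
        )
        out.append(
            TreatmentTimecourse(
                animal_id=f"{group}-{i + 1:02d}",
                group=group,
                timepoints_min=t,
                relative_intensity_pct=rel,
                relative_area_t0_pct=float(area),
            )
        )
    return out


def generate_scs_cohort(
    n_scs: int = 7,
    n_sham: int = 6,
    scs_preset: CohortPreset | str = "scs",
    sham_preset: CohortPreset | str = "sham",
    timepoints_min: Sequence[float] = DEFAULT_TIMEPOINTS_MIN,
    seed: int = 0,
) -> List[TreatmentTimecourse]:
    """Simulate the SCS (n = 7) and sham (n = 6) treatment arms.

    Before-treatment responses are 100 % by construction; post-treatment
    relative intensities follow each arm's preset at T = 0, 5, ..., 60
    minutes.  Values are left unclipped so slope recovery is unbiased.
    """
    if n_scs < 2 or n_sham < 2:
        raise ValueError("need at least 2 animals per arm")
    if isinstance(scs_preset, str):
        scs_preset = COHORT_PRESETS[scs_preset]
    if isinstance(sham_preset, str):
        sham_preset = COHORT_PRESETS[sham_preset]
    rng = np.random.default_rng(seed)
    cohort = _simulate_arm(n_scs, "SCS", scs_preset, timepoints_min, rng)
    cohort += _simulate_arm(n_sham, "sham", sham_preset, timepoints_min, rng)
    return cohort


# ---------------------------------------------------------------------------
# Behavioral cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorPreset:
    """Latent-trait model of the behavioral assays.

    Von Frey: each animal × day has a latent sensitivity on the filament
    index scale; withdrawal counts per filament are Binomial(5, p) with
    ``p = Φ((index - latent) / psychometric_scale)`` (a step function
    when the scale is 0), then reduced by the 3-of-5 rule, which snaps
    thresholds onto the filament series.  Neuropathy lowers the latent
    index by ``vf_shift_steps`` per post-operative day.

    Hotplate: latency = base − shift + animal effect + noise, floored at
    ``hp_floor_s`` and censored at 30 s.
    """

    vf_baseline_index: float = 7.0  # 15 g filament
    vf_shift_steps: Dict[int, float] = field(
        default_factory=lambda: {0: 0.0, 10: 2.5, 12: 3.0, 14: 3.5}
    )
    vf_sd_between: float = 0.4
    vf_sd_within: float = 0.4
    psychometric_scale: float = 0.5
    hp_baseline_s: float = 11.0
    hp_shift_s: Dict[int, float] = field(
        default_factory=lambda: {0: 0.0, 10: 3.5, 12: 4.0, 14: 4.5}
    )
    hp_sd_between: float = 1.0
    hp_sd_within: float = 1.5
    hp_floor_s: float = 1.0


def _vf_counts(latent: float, n_filaments: int, scale: float, rng) -> List[int]:
    idx = np.arange(n_filaments)
    if scale <= 0:
        p = (idx >= latent).astype(float)
    else:
        p = stats.norm.cdf((idx - latent) / scale)
    return [int(rng.binomial(5, pi)) for pi in p]


def generate_behavior_cohort(
    n: int = 18,
    neuropathy: bool = True,
    preset: Optional[BehaviorPreset] = None,
    filaments: FilamentSeries = FilamentSeries(),
    days: Sequence[int] = DAYS,
    seed: int = 0,
    group: str = "",
) -> List[BehavioralRecord]:
    """Simulate a behavioral cohort across testing days.

    With ``neuropathy=False`` (or with all shifts zero) every day shares
    the day-0 distributions — the null for calibration runs.  With all
    noise off the post-operative threshold equals the baseline filament
    shifted down by the configured number of steps exactly.
    """
    if n < 1:
        raise ValueError("need at least one animal")
    preset = preset or BehaviorPreset()
    rng = np.random.default_rng(seed)
    records: List[BehavioralRecord] = []
    nf = len(filaments.forces_g)
    for i in range(1, n + 1):
        vf_animal = rng.normal(0, preset.vf_sd_between) if preset.vf_sd_between > 0 else 0.0
        hp_animal = rng.normal(0, preset.hp_sd_between) if preset.hp_sd_between > 0 else 0.0
        for day in days:
            vf_shift = preset.vf_shift_steps.get(day, 0.0) if neuropathy else 0.0
            hp_shift = preset.hp_shift_s.get(day, 0.0) if neuropathy else 0.0
            vf_noise = rng.normal(0, preset.vf_sd_within) if preset.vf_sd_within > 0 else 0.0
            latent = preset.vf_baseline_index - vf_shift + vf_animal + vf_noise
            counts = _vf_counts(latent, nf, preset.psychometric_scale, rng)
            thr, censored = vonfrey_threshold(counts, filaments)

            hp_noise = rng.normal(0, preset.hp_sd_within) if preset.hp_sd_within > 0 else 0.0
            raw = max(preset.hp_floor_s, preset.hp_baseline_s - hp_shift + hp_animal + hp_noise)
            lat, hp_cens = hotplate_latency(raw)
            records.append(
                BehavioralRecord(
                    animal_id=f"rat-{i:02d}",
                    day=int(day),
                    vf_threshold_g=thr,
                    vf_censored_high=censored,
                    hp_latency_s=lat,
                    hp_censored=hp_cens,
                    group=group,
                )
            )
    return records


# Back-compat style alias used by the CLI
behavior_records = generate_behavior_cohort
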