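"""ROI metrics: traces, AFI intensity and area of excitation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinafi.dff import DffStack, compute_dff
from spinafi.roi import RoiSpec, afi_intensity, area_of_excitation, measure_response, roi_trace
from spinafi.simulate import SceneParams, render_movie


def make_dff(dff_array, valid=None, onset=2.0, pixel_size_um=10.0):
    dff_array = np.asarray(dff_array, float)
    T, H, W = dff_array.shape
    if valid is None:
        valid = np.ones((H, W), bool)
    return DffStack(
        dff=dff_array,
        f0=np.full((H, W), 1000.0),
        valid=valid,
        baseline_window=(0, 2),
        frame_times=np.arange(T, dtype=float),
        stim_onset=onset,
        stim_offset=onset + 1.0,
        pixel_size_um=pixel_size_um,
    )


def test_zero_dff_gives_zero_trace():
    d = make_dff(np.zeros((5, 8, 8)))
    tr = roi_trace(d, RoiSpec(center=(4, 4), size=4))
    assert np.all(tr.trace == 0.0)
    assert tr.n_valid_pixels == 16


def test_roi_trace_is_arithmetic_mean():
    arr = np.zeros((3, 4, 4))
    arr[1, 0:2, 0:2] = [[0.01, 0.02], [0.03, 0.04]]
    d = make_dff(arr)
    tr = roi_trace(d, RoiSpec(center=(1, 1), size=2))
    assert tr.trace[1] == pytest.approx(0.025)


def test_roi_trace_matches_double_loop_oracle(rng):
    arr = rng.normal(0, 0.01, size=(6, 10, 12))
    valid = rng.random((10, 12)) > 0.2
    d = make_dff(arr, valid=valid)
    roi = RoiSpec(center=(5, 6), size=5)
    tr = roi_trace(d, roi)
    r0, r1, c0, c1 = roi.bounds()
    for t in range(6):
        acc, n = 0.0, 0
        for r in range(r0, r1):
            for c in range(c0, c1):
                if valid[r, c]:
                    acc += arr[t, r, c]
                    n += 1
        assert tr.trace[t] == pytest.approx(acc / n, abs=1e-12)
    assert tr.n_valid_pixels == valid[r0:r1, c0:c1].sum()


def test_fully_masked_roi_rejected():
    d = make_dff(np.zeros((4, 6, 6)), valid=np.zeros((6, 6), bool))
    with pytest.raises(ValueError, match="no valid pixels"):
        roi_trace(d, RoiSpec(center=(3, 3), size=2))


def test_roi_out_of_bounds_rejected():
    d = make_dff(np.zeros((4, 6, 6)))
    with pytest.raises(ValueError, match="bounds"):
        roi_trace(d, RoiSpec(center=(0, 0), size=4))


def test_zero_stack_intensity_flagged_no_response():
    d = make_dff(np.zeros((6, 8, 8)))
    value, seg = afi_intensity(d, RoiSpec(center=(4, 4), size=4))
    assert value == 0.0
    assert seg.no_response


def test_intensity_recovers_injected_amplitude():
    """Noiseless rendered movie: ROI intensity equals the peak amplitude."""
    scene = SceneParams(noise_scale=0.0)
    stack, sidecar = render_movie(scene, "noxious-neuropathic", seed=0)
    d = compute_dff(stack)
    roi = RoiSpec(center=sidecar["center_ipsi"], size=scene.default_roi_size())
    value, seg = afi_intensity(d, roi)
    assert not seg.no_response
    assert value == pytest.approx(100.0 * sidecar["amp_ipsi"], abs=1e-6)


def test_on_blob_intensity_exceeds_off_blob():
    scene = SceneParams()
    stack, sidecar = render_movie(scene, "noxious-neuropathic", seed=42)
    d = compute_dff(stack)
    on, _ = afi_intensity(d, RoiSpec(center=sidecar["center_ipsi"], size=8))
    off, _ = afi_intensity(d, RoiSpec(center=(8, 8), size=8))
    assert on > off


# ---------------------------------------------------------------------------
# Area of excitation
# ---------------------------------------------------------------------------


def test_uniform_below_threshold_area_zero():
    d = make_dff(np.full((4, 8, 8), 0.001))
    area = area_of_excitation(d, 0.5, window=(2, 4))
    assert area.total_pixels == 0


def test_uniform_above_threshold_counts_everything():
    d = make_dff(np.full((4, 8, 10), 0.01))
    area = area_of_excitation(d, 0.5, window=(2, 4))
    assert area.total_pixels == 80
    assert area.ipsi_pixels == 40 and area.contra_pixels == 40
    assert area.total_mm2 == pytest.approx(80 * (10.0 / 1000.0) ** 2)


def test_area_matches_exhaustive_count(rng):
    arr = rng.normal(0, 0.004, size=(6, 16, 16))
    valid = rng.random((16, 16)) > 0.1
    d = make_dff(arr, valid=valid)
    area = area_of_excitation(d, 0.25, window=(2, 6))
    expected = 0
    for r in range(16):
        for c in range(16):
            if valid[r, c] and max(arr[t, r, c] for t in range(2, 6)) > 0.0025:
                expected += 1
    assert area.total_pixels == expected


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=0.05, max_value=2.0), st.floats(min_value=0.0, max_value=1.5))
def test_area_monotone_in_threshold(thr, delta):
    rng = np.random.default_rng(99)
    d = make_dff(rng.normal(0, 0.005, size=(5, 12, 12)))
    a1 = area_of_excitation(d, thr, window=(2, 5)).total_pixels
    a2 = area_of_excitation(d, thr + delta, window=(2, 5)).total_pixels
    assert a2 <= a1


def test_midline_split_is_exhaustive_and_disjoint(rng):
    d = make_dff(rng.normal(0, 0.005, size=(5, 14, 14)))
    area = area_of_excitation(d, 0.3, window=(2, 5))
    assert area.ipsi_pixels + area.contra_pixels == area.total_pixels
    # recompute ipsi by masking the contra half
    stat = d.dff[2:5].max(axis=0)
    ipsi_count = int(((stat[:7] > 0.003)).sum())
    assert area.ipsi_pixels == ipsi_count


def test_tie_at_threshold_not_counted():
    arr = np.zeros((3, 4, 4))
    arr[2, 1, 1] = 0.0025  # exactly the 0.25% level
    arr[2, 2, 2] = 0.00250001
    d = make_dff(arr)
    area = area_of_excitation(d, 0.25, window=(0, 3))
    assert area.total_pixels == 1


def test_blob_translation_shifts_supra_threshold_centroid():
    scene = SceneParams(noise_scale=0.0)
    dr, dc = -3, -4
    shifted = SceneParams(noise_scale=0.0, blob_center_ipsi=(16 + dr, 32 + dc))
    areas = []
    for sc in (scene, shifted):
        stack, sidecar = render_movie(sc, "noxious-neuropathic", seed=0)
        d = compute_dff(stack)
        stat = d.dff[(d.frame_times >= sc.stim_onset_s)].max(axis=0)
        supra = (stat > 0.0025) & d.valid
        supra[d.midline_row :] = False  # keep only the ipsi blob
        rr, cc = np.nonzero(supra)
        areas.append((rr.mean(), cc.mean()))
    assert areas[1][0] - areas[0][0] == pytest.approx(dr, abs=0.2)
    assert areas[1][1] - areas[0][1] == pytest.approx(dc, abs=0.2)


def test_empty_window_rejected():
    d = make_dff(np.zeros((4, 6, 6)))
    with pytest.raises(ValueError, match="window"):
        area_of_excitation(d, 0.25, window=(3, 3))
    with pytest.raises(ValueError, match="positive"):
        area_of_excitation(d, 0.0, window=(0, 2))


def test_measure_response_no_response_still_reports_area():
    d = make_dff(np.zeros((6, 8, 8)))
    resp = measure_response(d, RoiSpec(center=(4, 4), size=4))
    assert resp.no_response
    assert resp.area.total_pixels == 0
    assert resp.intensity_pct == 0.0
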