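"""Landmark detection, midsagittal plane fitting and slab reformatting."""

import numpy as np
import pytest

import mrpi2
from mrpi2.errors import StageFailure
from mrpi2.midsagittal import (build_axial_slab, detect_landmarks,
                               fit_midsagittal, _candidate_normal)
from mrpi2.preprocessing import normalize_intensity, register_rigid


def _process(vol):
    return normalize_intensity(register_rigid(vol, vol, mode="passthrough"))


def test_aqueduct_localization_untilted(landmarks, default_phantom):
    _, gt = default_phantom
    assert np.linalg.norm(landmarks.aqueduct_point - gt.aqueduct_point) <= 2.0
    assert all(c >= 0.5 for c in landmarks.confidence.values())


@pytest.mark.parametrize("tilt,noise", [
    ((0, 0, 0), 0.05), ((0, 5, 0), 0.0), ((0, -5, 0), 0.05), ((5, 0, 0), 0.05),
])
def test_aqueduct_localization_sweep(tilt, noise):
    vol, gt = mrpi2.generate_phantom(
        mrpi2.PhantomSpec(tilt_deg=tilt, noise_sd=noise, seed=2))
    lm = detect_landmarks(_process(vol))
    assert np.linalg.norm(lm.aqueduct_point - gt.aqueduct_point) <= 2.0


def test_landmark_dropout_fails_naming_aqueduct(default_phantom):
    vol, _ = default_phantom
    bad = mrpi2.corrupt_phantom(vol, "landmark_dropout", seed=0)
    with pytest.raises(StageFailure) as e:
        detect_landmarks(_process(bad))
    assert e.value.stage == "landmarks"
    assert "aqueduct" in str(e.value)


def test_mirrored_phantom_same_landmarks(default_phantom, landmarks):
    vol, _ = default_phantom
    mirrored = mrpi2.VolumeImage(vol.data[::-1].copy(), vol.affine.copy())
    lm_m = detect_landmarks(_process(mirrored))
    # midline structures are symmetric: landmarks agree within a voxel
    assert np.linalg.norm(lm_m.aqueduct_point - landmarks.aqueduct_point) <= 1.0
    assert np.linalg.norm(lm_m.cc_point - landmarks.cc_point) <= 1.0


def test_symmetric_phantom_plane_is_midline(msp, default_phantom):
    _, gt = default_phantom
    assert np.allclose(msp.normal, [1, 0, 0], atol=1e-6)
    assert abs(msp.origin[0] - gt.msp_origin[0]) <= 0.5
    # the plane passes within 2 mm of the aqueduct by construction
    assert abs(np.dot(msp.origin - gt.aqueduct_point, msp.normal)) <= 2.0


def test_plane_recovered_under_ap_tilt():
    vol, gt = mrpi2.generate_phantom(mrpi2.PhantomSpec(tilt_deg=(0, 5, 0)))
    canon = _process(vol)
    lm = detect_landmarks(canon)
    pl = fit_midsagittal(canon, lm)
    angle = np.degrees(np.arccos(np.clip(np.dot(pl.normal, gt.msp_normal), -1, 1)))
    assert min(angle, 180 - angle) <= 1.0


def test_plane_fit_deterministic(canonical, landmarks, msp):
    again = fit_midsagittal(canonical, landmarks)
    assert np.array_equal(again.normal, msp.normal)
    assert np.array_equal(again.origin, msp.origin)
    assert again.asymmetry == msp.asymmetry


def test_plane_asymmetry_is_minimal_over_rescan(canonical, landmarks, msp):
    """Exhaustive coarse re-scan never beats the returned plane's score."""
    data = canonical.data
    tissue = data > landmarks.csf_threshold
    vox = np.argwhere(tissue)
    vox = vox[::max(1, len(vox) // 8000)]
    pts = canonical.voxel_to_world(vox)
    vals = data[tuple(vox.T)]
    aq = landmarks.aqueduct_point
    best = msp.asymmetry
    for yaw in (-10.0, -5.0, 0.0, 5.0, 10.0):
        for roll in (-10.0, -5.0, 0.0, 5.0, 10.0):
            for off in (-2.0, -1.0, 0.0, 1.0, 2.0):
                n = _candidate_normal(yaw, roll)
                p0 = aq + off * n
                d = (pts - p0) @ n
                mirror = pts - 2.0 * d[:, None] * n
                ok = canonical.contains_world(mirror)
                score = float(np.mean(np.abs(
                    vals[ok] - canonical.sample_world(mirror[ok]))))
                assert score >= best - 1e-12


def test_slab_contract(slab):
    assert len(slab.slices) == 35
    assert slab.slice_mm == 1.0
    gaps = np.linalg.norm(np.diff(slab.centers, axis=0), axis=1)
    assert np.allclose(gaps, 1.0, atol=1e-9)
    # slices are parallel to the subcallosal line
    assert abs(np.dot(slab.stack_dir, slab.subcallosal_direction)) < 1e-9


def test_slab_axis_aligned_case(slab):
    # untilted phantom: stacking direction is the inferior axis
    assert np.allclose(slab.stack_dir, [0, 0, -1], atol=1e-6)


def test_slab_covers_widest_v3_level(slab, default_phantom):
    _, gt = default_phantom
    lo, hi = gt.v3_widest_z
    zs = slab.centers[:, 2]
    assert ((zs >= lo) & (zs <= hi)).any()


def test_slab_out_of_bounds_fails(canonical, landmarks, msp):
    with pytest.raises(StageFailure) as e:
        build_axial_slab(canonical, landmarks, msp, n_slices=35, slice_mm=10.0)
    assert e.value.stage == "slab"
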