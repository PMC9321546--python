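"""Spatial/intensity normalization: rigid registration recovery, isotropic
resampling, robust percentile intensity scaling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mrpi2
from mrpi2.errors import StageFailure
from mrpi2.preprocessing import (CanonicalVolume, normalize_intensity,
                                 register_rigid, resample_isotropic)
from mrpi2.volume import VolumeImage, centered_affine


def _canon(data):
    return CanonicalVolume(np.asarray(data, dtype=np.float32),
                           centered_affine(data.shape, 1.0))


def test_normalize_two_point_range():
    data = np.zeros((8, 8, 8), dtype=np.float32)
    data[2:6, 2:6, 2:6] = 100.0
    out = normalize_intensity(_canon(data))
    assert set(np.unique(out.data)) == {0.0, 1.0}


def test_normalize_bounds_and_monotone():
    rng = np.random.default_rng(0)
    data = rng.gamma(2.0, 50.0, (20, 20, 20)).astype(np.float32)
    out = normalize_intensity(_canon(data))
    assert out.data.min() >= 0.0 and out.data.max() <= 1.0
    # monotone: rank order preserved up to clipping ties
    flat_in, flat_out = data.ravel(), out.data.ravel()
    order = np.argsort(flat_in)
    assert (np.diff(flat_out[order]) >= -1e-7).all()


def test_normalize_idempotent():
    rng = np.random.default_rng(1)
    data = rng.random((16, 16, 16)).astype(np.float32) * 200
    once = normalize_intensity(_canon(data))
    twice = normalize_intensity(once)
    assert np.abs(twice.data - once.data).max() <= 1e-6


def test_normalize_constant_image_fails():
    with pytest.raises(StageFailure) as e:
        normalize_intensity(_canon(np.full((8, 8, 8), 3.0)))
    assert e.value.stage == "intensity"


def test_normalize_outlier_robust():
    # one hot voxel must not move the 99th-percentile anchor appreciably
    data = np.zeros((128, 128, 128), dtype=np.float32)
    data[20:100, 20:100, 20:100] = 1000.0
    ref = normalize_intensity(_canon(data))
    spiked = data.copy()
    spiked[5, 5, 5] = 1e6
    out = normalize_intensity(_canon(spiked))
    tissue = ref.data[50, 50, 50]
    assert abs(out.data[50, 50, 50] - tissue) / tissue < 0.01


def test_resample_noop_and_anisotropic():
    vol, _ = mrpi2.generate_phantom(mrpi2.PhantomSpec())
    same = resample_isotropic(vol, 1.0)
    assert same.shape == vol.shape and np.allclose(same.data, vol.data)
    aniso = VolumeImage(vol.data[:, :, ::3].copy(),
                        vol.affine @ np.diag([1, 1, 3, 1]))
    iso = resample_isotropic(aniso, 1.0)
    assert np.allclose(iso.spacing, 1.0)


def test_halfmm_phantom_resampled_recovers_widths():
    spec = mrpi2.PhantomSpec(voxel_mm=0.5, v3_width_mm=8.61, fh_width_mm=39.1)
    vol, gt = mrpi2.generate_phantom(spec)
    iso = resample_isotropic(vol, 1.0)
    assert np.allclose(iso.spacing, 1.0)
    res = mrpi2.run_subject(iso)
    assert res.status == "ok"
    assert abs(res.measures["v3_width_mm"] - gt.v3_width_mm) <= 1.0
    assert abs(res.measures["fh_width_mm"] - gt.fh_width_mm) <= 1.0


def test_rigid_registration_recovers_rotation():
    template, _ = mrpi2.generate_phantom(mrpi2.PhantomSpec())
    tilted, _ = mrpi2.generate_phantom(mrpi2.PhantomSpec(tilt_deg=(5, 5, 5)))
    canon = register_rigid(tilted, template, mode="rigid")
    rec = np.array(canon.meta["registration_rotation_ras"])
    true = Rotation.from_euler("xyz", (5, 5, 5), degrees=True).as_matrix()
    err = Rotation.from_matrix(rec @ true.T).as_euler("xyz", degrees=True)
    assert np.abs(err).max() <= 0.5


def test_registration_roundtrip_preserves_measurements():
    # known rotation + registration back: linear measures within one voxel,
    # areas within 5%
    template, gt0 = mrpi2.generate_phantom(mrpi2.PhantomSpec())
    tilted, _ = mrpi2.generate_phantom(mrpi2.PhantomSpec(tilt_deg=(4, -3, 5)))
    canon = register_rigid(tilted, template, mode="rigid")
    res = mrpi2.run_subject(VolumeImage(canon.data, canon.affine))
    assert res.status == "ok"
    m = res.measures
    assert abs(m["v3_width_mm"] - gt0.v3_width_mm) <= 1.0
    assert abs(m["fh_width_mm"] - gt0.fh_width_mm) <= 1.0
    assert abs(m["midbrain_area_mm2"] / gt0.midbrain_area_mm2 - 1) <= 0.05
    assert abs(m["pons_area_mm2"] / gt0.pons_area_mm2 - 1) <= 0.05


def test_degenerate_template_fails():
    vol, _ = mrpi2.generate_phantom(mrpi2.PhantomSpec())
    zeros = VolumeImage(np.zeros_like(vol.data), vol.affine)
    with pytest.raises(StageFailure) as e:
        register_rigid(vol, zeros, mode="rigid")
    assert e.value.stage == "registration"


def test_passthrough_is_identity_resampling():
    vol, _ = mrpi2.generate_phantom(mrpi2.PhantomSpec())
    canon = register_rigid(vol, vol, mode="passthrough")
    assert np.allclose(canon.data, vol.data)
    assert canon.registration_transform == (0.0,) * 6
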