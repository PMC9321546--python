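"""Brainstem profile segmentation, midbrain/pons split, peduncle widths, MRPI."""

import numpy as np
import pytest

import mrpi2
from mrpi2 import brainstem as bs
from mrpi2.errors import StageFailure
from mrpi2.midsagittal import MidsagittalPlane
from mrpi2.sampling import PlanarImage


@pytest.fixture(scope="module")
def brainstem_seg(msp, landmarks):
    return bs.segment_brainstem_midsagittal(msp, landmarks)


def test_segmentation_total_area(brainstem_seg, default_phantom):
    _, gt = default_phantom
    total_true = gt.midbrain_area_mm2 + gt.pons_area_mm2
    assert abs(brainstem_seg.area_mm2 / total_true - 1) <= 0.05


def test_segmentation_is_single_component(brainstem_seg):
    from scipy import ndimage
    _, n = ndimage.label(brainstem_seg.mask)
    assert n == 1


def test_all_csf_slice_fails(msp, landmarks):
    img = msp.slice2d
    flat = PlanarImage(np.zeros_like(img.data), img.origin, img.e1, img.e2,
                       img.u_min, img.v_min, img.step)
    fake = MidsagittalPlane(origin=msp.origin, normal=msp.normal,
                            slice2d=flat, asymmetry=0.0, tilt_deg=(0, 0))
    with pytest.raises(StageFailure) as e:
        bs.segment_brainstem_midsagittal(fake, landmarks)
    assert e.value.stage == "brainstem"


def test_split_recovers_constructed_areas(brainstem_seg, landmarks, default_phantom):
    _, gt = default_phantom
    mb, pons, line = bs.split_midbrain_pons(brainstem_seg, landmarks)
    assert abs(mb / gt.midbrain_area_mm2 - 1) <= 0.05
    assert abs(pons / gt.pons_area_mm2 - 1) <= 0.05
    # the boundary line sits at the constructed junction level
    assert abs(line[0][2] - gt.junction_z) <= 0.5


def test_split_partition_is_exact(brainstem_seg, landmarks):
    mb, pons, _ = bs.split_midbrain_pons(brainstem_seg, landmarks)
    total = float(brainstem_seg.mask.sum()) * brainstem_seg.image.pixel_area
    assert mb + pons == pytest.approx(total, abs=1e-9)


def test_notchless_profile_fails(brainstem_seg, landmarks):
    # a rectangular profile has no interior anterior concavity
    rect = np.zeros_like(brainstem_seg.mask)
    rect[40:140, 60:160] = True
    fake = bs.PlanarMask(mask=rect, image=brainstem_seg.image,
                         threshold=brainstem_seg.threshold)
    with pytest.raises(StageFailure):
        bs.split_midbrain_pons(fake, landmarks)


def test_mcp_width_and_symmetry(canonical, msp, landmarks, default_phantom):
    _, gt = default_phantom
    left, right, mean = bs.measure_mcp(canonical, msp, landmarks)
    assert abs(mean - gt.mcp_width_mm) <= 1.0
    assert abs(left - right) <= 1.0  # symmetric phantom: one voxel
    again = bs.measure_mcp(canonical, msp, landmarks)
    assert again == (left, right, mean)


def test_scp_width_and_ordering(canonical, msp, landmarks, default_phantom):
    _, gt = default_phantom
    left, right, mean = bs.measure_scp(canonical, msp, landmarks)
    assert abs(mean - gt.scp_width_mm) <= 1.0
    assert abs(left - right) <= 1.0
    _, _, mcp_mean = bs.measure_mcp(canonical, msp, landmarks)
    assert mean < mcp_mean  # constructed SCP < MCP ordering preserved


def _measures(pons, mb, mcp, scp):
    return bs.BrainstemMeasures(midbrain_area_mm2=mb, pons_area_mm2=pons,
                                mcp_left_mm=mcp, mcp_right_mm=mcp, mcp_mean_mm=mcp,
                                scp_left_mm=scp, scp_right_mm=scp, scp_mean_mm=scp,
                                boundary_line=((0, 0, 0), (0, 0, 0)))


def test_mrpi_arithmetic():
    # (520/105) * (9.2/3.2) = 14.2381...; the magnitude reported for
    # PSP-P cohorts (MRPI ~ 14.3)
    val = bs.compute_mrpi(_measures(520.0, 105.0, 9.2, 3.2))
    assert val == pytest.approx((520.0 / 105.0) * (9.2 / 3.2), rel=1e-12)
    assert bs.compute_mrpi(_measures(100.0, 100.0, 5.0, 5.0)) == 1.0
    assert bs.compute_mrpi(_measures(1040.0, 105.0, 9.2, 3.2)) == \
        pytest.approx(2 * val, rel=1e-12)


def test_mrpi_rejects_nonpositive():
    with pytest.raises((ValueError, StageFailure)):
        bs.compute_mrpi(_measures(520.0, 105.0, 9.2, -1.0))


def test_mirrored_volume_swaps_sides(default_phantom):
    vol, _ = default_phantom
    from mrpi2.midsagittal import detect_landmarks, fit_midsagittal
    from mrpi2.preprocessing import normalize_intensity, register_rigid
    mirrored = mrpi2.VolumeImage(vol.data[::-1].copy(), vol.affine.copy())
    canon_m = normalize_intensity(register_rigid(mirrored, mirrored,
                                                 mode="passthrough"))
    lm = detect_landmarks(canon_m)
    pl = fit_midsagittal(canon_m, lm)
    l_m, r_m, mean_m = bs.measure_mcp(canon_m, pl, lm)
    canon = normalize_intensity(register_rigid(vol, vol, mode="passthrough"))
    lm0 = detect_landmarks(canon)
    pl0 = fit_midsagittal(canon, lm0)
    l0, r0, mean0 = bs.measure_mcp(canon, pl0, lm0)
    assert mean_m == pytest.approx(mean0, abs=1e-6)
    assert sorted([l_m, r_m]) == pytest.approx(sorted([l0, r0]), abs=1e-6)
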