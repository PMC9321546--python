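"""Spatial and intensity normalization into the canonical measurement space.

All morphometry downstream assumes a 1 mm isotropic, template-aligned (RAS)
grid with intensities on [0, 1].  Spatial normalization is a six-parameter
rigid transform (three rotations, three translations): the measurements are
absolute millimetres, so scaling must never be applied.  Registration is
delegated to SimpleITK (Euler3D transform, Mattes mutual information,
three-level multi-resolution descent); a pass-through mode skips
optimization for inputs already in canonical pose (e.g. phantoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import StageFailure
from .volume import VolumeImage, centered_affine

_SAMPLING_SEED = 121212  # fixed metric-sampling seed: registration stays deterministic


@dataclass
class CanonicalVolume(VolumeImage):
    """A volume resampled to the 1 mm isotropic canonical grid.

    ``registration_transform`` is the applied 6-DOF rigid transform as a
    (rx, ry, rz, tx, ty, tz) tuple (radians, mm); ``registration_cost`` the
    final similarity value (0.0 in pass-through mode).
    """

    registration_transform: tuple = (0.0,) * 6
    registration_cost: float = 0.0

    def __post_init__(self):
        super().__post_init__()
        if not np.allclose(self.spacing, 1.0, atol=1e-6):
            raise ValueError("CanonicalVolume requires exactly 1 mm isotropic spacing")


def _to_sitk(vol: VolumeImage) -> sitk.Image:
    # sitk uses LPS world coordinates and xyz-index order; our arrays are
    # RAS ijk-ordered with axis-aligned affines, so flip the first two axes' signs.
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    origin = vol.affine[:3, 3]
    img.SetOrigin((-float(origin[0]), -float(origin[1]), float(origin[2])))
    img.SetDirection((-1.0, 0, 0, 0, -1.0, 0, 0, 0, 1.0))
    return img


def resample_isotropic(volume: VolumeImage, target_mm: float) -> VolumeImage:
    """Trilinear resampling onto an isotropic grid preserving world extent."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    spacing = volume.spacing
    if np.allclose(spacing, target_mm, atol=1e-9):
        return volume.copy()
    shape = np.asarray(volume.shape)
    extent = shape * spacing
    new_shape = np.maximum(np.round(extent / target_mm).astype(int), 1)
    # voxel-center grid of the new image, expressed in old voxel coordinates
    scale = target_mm / spacing
    grids = [(np.arange(ns) + 0.5) * sc - 0.5 for ns, sc in zip(new_shape, scale)]
    coords = np.meshgrid(*grids, indexing="ij")
    data = ndimage.map_coordinates(volume.data, np.array(coords), order=1,
                                   mode="constant", cval=0.0)
    new_aff = volume.affine.copy()
    new_aff[:3, :3] = volume.affine[:3, :3] @ np.diag(scale)
    # keep the first voxel-center mapping consistent with the shifted grid
    shift = volume.affine[:3, :3] @ ((scale - 1) / 2.0)
    new_aff[:3, 3] = volume.affine[:3, 3] + shift
    return VolumeImage(data.astype(np.float32), new_aff, dict(volume.meta))


def register_rigid(volume: VolumeImage, template: VolumeImage,
                   mode: str = "rigid", metric: str = "mattes_mi") -> CanonicalVolume:
    """Align a volume to a template with a 6-DOF rigid transform.

    ``mode="passthrough"`` applies the identity transform (resampling to
    1 mm only), for inputs already in canonical pose.  Raises
    :class:`StageFailure` (stage ``"registration"``) on degenerate input or
    non-convergence.
    """
    if mode == "passthrough":
        iso = resample_isotropic(volume, 1.0)
        return CanonicalVolume(iso.data, iso.affine, dict(volume.meta))
    if mode != "rigid":
        raise ValueError(f"unknown registration mode {mode!r}")
    if float(np.ptp(template.data)) <= 0 or float(np.ptp(volume.data)) <= 0:
        raise StageFailure("registration", "degenerate (constant) volume or template")

    fixed = sitk.Cast(_to_sitk(template), sitk.sitkFloat32)
    moving = sitk.Cast(_to_sitk(volume), sitk.sitkFloat32)
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)

    reg = sitk.ImageRegistrationMethod()
    if metric == "mattes_mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    elif metric == "correlation":
        reg.SetMetricAsCorrelation()
    elif metric == "mean_squares":
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown registration metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.25, _SAMPLING_SEED)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=300,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init, inPlace=False)
    try:
        transform = reg.Execute(fixed, moving)
        cost = float(reg.GetMetricValue())
    except RuntimeError as exc:
        raise StageFailure("registration", f"optimizer failed: {exc}") from exc

    # Resample the moving image onto the template-aligned 1 mm canonical grid.
    extent = np.asarray(template.shape) * template.spacing
    out_shape = np.round(extent).astype(int)
    ref = sitk.Image([int(s) for s in out_shape], sitk.sitkFloat32)
    ref.SetSpacing((1.0, 1.0, 1.0))
    canon_aff = centered_affine(out_shape, 1.0)
    canon_aff[:3, 3] += template.world_center()
    ref.SetOrigin((-float(canon_aff[0, 3]), -float(canon_aff[1, 3]), float(canon_aff[2, 3])))
    ref.SetDirection((-1.0, 0, 0, 0, -1.0, 0, 0, 0, 1.0))
    resampled = sitk.Resample(moving, ref, transform, sitk.sitkLinear, 0.0)
    data = sitk.GetArrayFromImage(resampled).T.astype(np.float32)

    euler = sitk.Euler3DTransform()
    flat = transform if isinstance(transform, sitk.Euler3DTransform) else \
        sitk.CompositeTransform(transform).GetNthTransform(0)
    euler.SetParameters(flat.GetParameters())
    params = tuple(float(p) for p in euler.GetParameters())
    # store the recovered rotation in RAS world coordinates for inspection
    flip = np.diag([-1.0, -1.0, 1.0])
    rot_lps = np.array(euler.GetMatrix()).reshape(3, 3)
    meta = dict(volume.meta)
    meta["registration_rotation_ras"] = (flip @ rot_lps @ flip).tolist()
    return CanonicalVolume(data, canon_aff, meta,
                           registration_transform=params, registration_cost=cost)


def builtin_template() -> VolumeImage:
    """Noise-free schematic template in canonical pose (no download needed).

    Generated by the phantom module; callers working with real data should
    supply an MNI template volume instead.
    """
    from .phantom import PhantomSpec, generate_phantom

    vol, _ = generate_phantom(PhantomSpec(noise_sd=0.0, seed=0))
    return vol


def normalize_intensity(volume: CanonicalVolume,
                        clip_percentiles: tuple = (1.0, 99.0)) -> CanonicalVolume:
    """Robust percentile rescaling of intensities to [0, 1].

    Anchors are the given percentiles of the nonzero voxels; the mapping is
    monotone (rank order preserved up to clipping).  Normalization state is
    recorded in ``meta`` so re-application is an exact no-op (idempotence).
    Raises :class:`StageFailure` (stage ``"intensity"``) on constant images.
    """
    if volume.meta.get("intensity_normalized"):
        return volume
    if float(np.ptp(volume.data)) <= 0:
        raise StageFailure("intensity", "constant image: no intensity range")
    lo, hi = np.percentile(volume.data, clip_percentiles)
    if hi <= lo:
        # percentile anchors collapse (e.g. dominant uniform background):
        # fall back to the full range
        lo, hi = float(volume.data.min()), float(volume.data.max())
    if hi <= lo:
        raise StageFailure("intensity", "degenerate percentile anchors")
    data = np.clip((volume.data - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
    meta = dict(volume.meta)
    meta["intensity_normalized"] = True
    return CanonicalVolume(data, volume.affine.copy(), meta,
                           registration_transform=volume.registration_transform,
                           registration_cost=volume.registration_cost)
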