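"""3D scalar volumes with world-space geometry, backed by NIfTI-1 files.

The in-memory container is a thin dataclass around a float array, a
grid-to-world affine and per-axis voxel spacing.  All geometry downstream
(landmarks, planes, measurements) is expressed in world millimetres; images
are reoriented to RAS on load so that +x is subject-left-to-right, +y is
posterior-to-anterior and +z is inferior-to-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import VolumeIOError


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel spacing (mm) and a grid-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage requires a 3D array")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (always positive)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def sample_world(self, points_mm: np.ndarray, order: int = 1,
                     cval: float = 0.0) -> np.ndarray:
        """Interpolate intensities at world-space points (trilinear by default)."""
        vox = self.world_to_voxel(points_mm)
        return ndimage.map_coordinates(self.data, vox.T, order=order,
                                       mode="constant", cval=cval)

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.data.copy(), self.affine.copy(), dict(self.meta))

    def world_center(self) -> np.ndarray:
        return self.voxel_to_world((np.asarray(self.shape) - 1) / 2.0)[0]

    def contains_world(self, points_mm: np.ndarray) -> np.ndarray:
        vox = self.world_to_voxel(points_mm)
        shp = np.asarray(self.shape)
        return np.all((vox >= -0.5) & (vox <= shp - 0.5), axis=1)


def centered_affine(shape, spacing_mm) -> np.ndarray:
    """Axis-aligned RAS affine placing the volume center at world (0,0,0)."""
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = -(np.asarray(shape) - 1) * spacing / 2.0
    return aff


def read_volume(path) -> VolumeImage:
    """Load a NIfTI-1/2 volume (gzipped or not), reoriented to RAS.

    Honors the qform/sform affine; raises :class:`VolumeIOError` with the
    filename for malformed or truncated files.
    """
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)  # RAS+
        data = np.asanyarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VolumeImage(data, img.affine, meta={"source": str(path)})


def write_volume(vol: VolumeImage, path) -> None:
    """Write as NIfTI-1 with the volume's affine and spacing."""
    try:
        img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
        img.header.set_zooms(tuple(vol.spacing))
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write volume {path}: {exc}") from exc
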