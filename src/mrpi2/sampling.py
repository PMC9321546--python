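"""Oblique plane resampling and sub-voxel linear measurement primitives."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VolumeImage


@dataclass
class PlanarImage:
    """A 2D image resampled on an arbitrary plane of a volume.

    ``data[i, j]`` lives at world point ``origin + u(i)*e1 + v(j)*e2`` with
    ``u(i) = u_min + i*step`` and ``v(j) = v_min + j*step``.
    """

    data: np.ndarray
    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    u_min: float
    v_min: float
    step: float

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.e1, self.e2)

    def uv_of_index(self, i, j):
        return self.u_min + np.asarray(i) * self.step, \
               self.v_min + np.asarray(j) * self.step

    def uv_to_world(self, u, v) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        return self.origin + np.outer(u, self.e1) + np.outer(v, self.e2)

    def world_to_uv(self, points: np.ndarray):
        rel = np.atleast_2d(points) - self.origin
        return rel @ self.e1, rel @ self.e2

    def sample_uv(self, u, v) -> np.ndarray:
        """Bilinear interpolation of the plane image at in-plane coordinates."""
        i = (np.asarray(u, dtype=float) - self.u_min) / self.step
        j = (np.asarray(v, dtype=float) - self.v_min) / self.step
        return ndimage.map_coordinates(self.data, np.vstack([np.ravel(i), np.ravel(j)]),
                                       order=1, mode="constant", cval=0.0)

    @property
    def pixel_area(self) -> float:
        return self.step ** 2


def sample_plane(vol: VolumeImage, origin, e1, e2, u_range, v_range,
                 step: float) -> PlanarImage:
    """Resample a volume on the plane spanned by unit vectors e1, e2."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    origin = np.asarray(origin, dtype=float)
    us = np.arange(u_range[0], u_range[1] + step / 2, step)
    vs = np.arange(v_range[0], v_range[1] + step / 2, step)
    U, V = np.meshgrid(us, vs, indexing="ij")
    pts = origin + U[..., None] * e1 + V[..., None] * e2
    vals = vol.sample_world(pts.reshape(-1, 3)).reshape(U.shape)
    return PlanarImage(vals.astype(np.float32), origin, e1, e2,
                       float(us[0]), float(vs[0]), float(step))


def run_bounds(ts: np.ndarray, values: np.ndarray, thr: float, t_center: float,
               above: bool = True):
    """Sub-sample bounds of the thresholded run containing ``t_center``.

    ``values`` are intensities sampled at positions ``ts`` along a line;
    the contiguous run of samples (above or below ``thr``) containing the
    sample nearest ``t_center`` is located and both endpoints are refined
    by linear interpolation of the threshold crossing.  Returns
    ``(t_lo, t_hi)`` or ``None`` when the center sample is off-class.
    """
    mask = values > thr if above else values < thr
    k = int(np.argmin(np.abs(ts - t_center)))
    if not mask[k]:
        return None
    lo = k
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = k
    while hi < len(ts) - 1 and mask[hi + 1]:
        hi += 1

    def cross(i_in, i_out):
        if i_out < 0 or i_out >= len(ts):
            return ts[i_in]
        v_in, v_out = values[i_in], values[i_out]
        if v_in == v_out:
            return (ts[i_in] + ts[i_out]) / 2.0
        f = (thr - v_in) / (v_out - v_in)
        return ts[i_in] + f * (ts[i_out] - ts[i_in])

    return float(cross(lo, lo - 1)), float(cross(hi, hi + 1))


def csf_tissue_threshold(data: np.ndarray) -> float:
    """Midpoint threshold between CSF-like and tissue-like intensity modes.

    Uses the 99th percentile of nonzero voxels as the bright anchor, then
    places the threshold halfway between the median bright-class and the
    median dark-but-nonbackground intensity.  Sub-voxel edge interpolation
    at this threshold lands on the geometric tissue/CSF interface.
    """
    nz = data[data > 0]
    if nz.size == 0:
        return 0.5
    p99 = float(np.percentile(nz, 99))
    bright = data[data > 0.5 * p99]
    mu_t = float(np.median(bright)) if bright.size else p99
    dark = data[(data > 0.02 * p99) & (data <= 0.5 * p99)]
    mu_c = float(np.median(dark)) if dark.size else 0.0
    return 0.5 * (mu_t + mu_c)
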