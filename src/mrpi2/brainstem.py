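"""Brainstem morphometry: midbrain/pons areas, peduncle widths, MRPI.

The Magnetic Resonance Parkinsonism Index is

    MRPI = (pons area / midbrain area) * (MCP width / SCP width)

with areas measured on the midsagittal plane and the middle / superior
cerebellar peduncle (MCP / SCP) widths on parasagittal and posterior
coronal reformats.  The midbrain/pons boundary is a straight line through
the pontomesencephalic junction notch — the deepest anterior concavity of
the brainstem profile — oriented along the anteroposterior axis of the
midsagittal slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import StageFailure
from .midsagittal import LandmarkSet, MidsagittalPlane
from .preprocessing import CanonicalVolume
from .sampling import PlanarImage, run_bounds, sample_plane

# Search boxes in slice coordinates relative to the aqueduct landmark (mm).
BRAINSTEM_BOX_U = (-25.0, 27.0)   # anteroposterior
BRAINSTEM_BOX_V = (-32.0, 8.0)    # inferosuperior
MCP_BOX_V = (-28.0, -3.0)
SCP_BOX_U = (-20.0, 20.0)
SCP_BOX_V = (-8.0, 8.0)
WIDTH_SANITY_MM = 30.0


@dataclass
class BrainstemMeasures:
    midbrain_area_mm2: float
    pons_area_mm2: float
    mcp_left_mm: float
    mcp_right_mm: float
    mcp_mean_mm: float
    scp_left_mm: float
    scp_right_mm: float
    scp_mean_mm: float
    boundary_line: tuple

    def __post_init__(self):
        for w in (self.mcp_mean_mm, self.scp_mean_mm):
            if not (0 < w <= WIDTH_SANITY_MM):
                raise StageFailure("brainstem", f"implausible peduncle width {w:.1f} mm")
        if self.midbrain_area_mm2 <= 0 or self.pons_area_mm2 <= 0:
            raise StageFailure("brainstem", "non-positive profile area")


@dataclass
class PlanarMask:
    """A binary component on a resampled plane."""

    mask: np.ndarray
    image: PlanarImage
    threshold: float

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.image.pixel_area


def segment_brainstem_midsagittal(plane: MidsagittalPlane,
                                  landmarks: LandmarkSet) -> PlanarMask:
    """Segment the brainstem profile on the midsagittal slice.

    Otsu-derived threshold restricted to a search box around the landmarks;
    returns the connected tissue component containing the upper-brainstem
    landmark.  The slice coordinate origin is the aqueduct point, so the
    search box is anatomy-anchored.
    """
    img = plane.slice2d
    us, vs = np.meshgrid(
        img.u_min + np.arange(img.data.shape[0]) * img.step,
        img.v_min + np.arange(img.data.shape[1]) * img.step, indexing="ij")
    box = ((us >= BRAINSTEM_BOX_U[0]) & (us <= BRAINSTEM_BOX_U[1])
           & (vs >= BRAINSTEM_BOX_V[0]) & (vs <= BRAINSTEM_BOX_V[1]))
    pixels = img.data[box]
    if pixels.size == 0 or float(np.ptp(pixels)) <= 0:
        raise StageFailure("brainstem", "empty brainstem search box")
    try:
        t0 = threshold_otsu(pixels)
    except ValueError as exc:
        raise StageFailure("brainstem", "threshold failure in search box") from exc
    lowers, uppers = pixels[pixels <= t0], pixels[pixels > t0]
    if uppers.size == 0:
        raise StageFailure("brainstem", "all-CSF search box: no tissue")
    thr = 0.5 * ((float(lowers.mean()) if lowers.size else 0.0) + float(uppers.mean()))

    tissue = (img.data > thr) & box
    labels, n = ndimage.label(tissue)
    if n == 0:
        raise StageFailure("brainstem", "no tissue component in search box")
    bu, bv = img.world_to_uv(landmarks.brainstem_point)
    i = int(round((bu[0] - img.u_min) / img.step))
    j = int(round((bv[0] - img.v_min) / img.step))
    i = np.clip(i, 0, labels.shape[0] - 1)
    j = np.clip(j, 0, labels.shape[1] - 1)
    lab = labels[i, j]
    if lab == 0:
        raise StageFailure("brainstem", "brainstem landmark not inside tissue")
    return PlanarMask(mask=labels == lab, image=img, threshold=float(thr))


def split_midbrain_pons(seg: PlanarMask, landmarks: LandmarkSet):
    """Divide the brainstem profile at the pontomesencephalic junction notch.

    The dividing line runs along the anteroposterior slice axis through the
    deepest anterior concavity of the profile; areas are pixel counts times
    pixel area, so midbrain + pons always partitions the mask exactly.
    Returns ``(midbrain_area_mm2, pons_area_mm2, boundary_line)``.
    """
    img, mask = seg.image, seg.mask
    rows = np.flatnonzero(mask.any(axis=0))  # v-rows containing mask
    if len(rows) < 9:
        raise StageFailure("brainstem", "brainstem profile too short to split")
    interior = rows[2:-2]
    front = np.array([np.max(np.flatnonzero(mask[:, j])) for j in interior])
    fmin = front.min()
    at_min = front == fmin
    if at_min[0] or at_min[-1]:
        raise StageFailure("brainstem", "junction notch not found (no interior concavity)")
    runs = np.flatnonzero(at_min)
    # longest contiguous run of minimal anterior extent
    splits = np.split(runs, np.flatnonzero(np.diff(runs) > 1) + 1)
    run = max(splits, key=len)
    k = interior[run[0] + len(run) // 2]

    upper = mask[:, k:]
    lower = mask[:, :k]
    mb_area = float(upper.sum()) * img.pixel_area
    pons_area = float(lower.sum()) * img.pixel_area
    if mb_area <= 0 or pons_area <= 0:
        raise StageFailure("brainstem", "degenerate midbrain/pons partition")
    v_line = img.v_min + (k - 0.5) * img.step
    cols = np.flatnonzero(mask.any(axis=1))
    p_left = img.uv_to_world(img.u_min + cols[0] * img.step, v_line)[0]
    p_right = img.uv_to_world(img.u_min + cols[-1] * img.step, v_line)[0]
    return mb_area, pons_area, (tuple(p_left), tuple(p_right))


def _component_width(img: PlanarImage, mask: np.ndarray, thr: float,
                     n_stations: int = 9, ray_half_mm: float = 15.0):
    """Narrowest width of a bar-like component over the middle third of its axis.

    The component's principal axis is estimated from its pixel coordinates;
    perpendicular widths are measured at evenly spaced stations with
    sub-pixel threshold-crossing interpolation, and the minimum over the
    middle third is returned (avoids flaring ends).  ``None`` if fewer than
    three stations yield a valid crossing.
    """
    px = np.argwhere(mask)
    if len(px) < 8:
        return None
    uv = np.column_stack([img.u_min + px[:, 0] * img.step,
                          img.v_min + px[:, 1] * img.step])
    center = uv.mean(axis=0)
    cov = np.cov((uv - center).T)
    w_eig, v_eig = np.linalg.eigh(cov)
    axis = v_eig[:, -1]          # long axis
    perp = v_eig[:, 0]
    t = (uv - center) @ axis
    t0, t1 = t.min(), t.max()
    span = t1 - t0
    stations = np.linspace(t0 + span / 3.0, t1 - span / 3.0, n_stations)
    ss = np.arange(-ray_half_mm, ray_half_mm + 1e-9, 0.1)
    widths = []
    for st in stations:
        c = center + st * axis
        pts_u = c[0] + ss * perp[0]
        pts_v = c[1] + ss * perp[1]
        vals = img.sample_uv(pts_u, pts_v)
        run = run_bounds(ss, vals, thr, 0.0, above=True)
        if run is not None:
            widths.append(run[1] - run[0])
    if len(widths) < 3:
        return None
    return float(min(widths))


def _side_slice_width(volume, origin, e1, e2, u_box, v_box, thr, step=0.25):
    h = step / 2.0
    img = sample_plane(volume, origin, e1, e2,
                       (u_box[0] + h, u_box[1] + h), (v_box[0] + h, v_box[1] + h), step)
    tissue = img.data > thr
    labels, n = ndimage.label(tissue)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    lab = int(np.argmax(sizes)) + 1
    return _component_width(img, labels == lab, thr)


def measure_mcp(volume: CanonicalVolume, plane: MidsagittalPlane,
                landmarks: LandmarkSet, offset_mm: float = 12.0):
    """Middle cerebellar peduncle widths on left/right parasagittal slices.

    Slices lie at a fixed offset from the midsagittal plane; the peduncle
    bar is segmented by threshold and its width taken at the narrowest
    point of the middle third of its long axis.  Returns
    ``(left, right, mean)`` in mm; a side that cannot be measured is NaN,
    and failure is raised only when neither side is found.
    """
    thr = landmarks.csf_threshold
    img0 = plane.slice2d
    sides = {}
    for name, sign in (("left", -1.0), ("right", 1.0)):
        origin = plane.origin + sign * offset_mm * plane.normal
        sides[name] = _side_slice_width(
            volume, origin, img0.e1, img0.e2,
            BRAINSTEM_BOX_U, MCP_BOX_V, thr)
    found = [v for v in sides.values() if v is not None]
    if not found:
        raise StageFailure("brainstem", "middle cerebellar peduncle not found on either side")
    mean = float(np.mean(found))
    return (sides["left"] if sides["left"] is not None else np.nan,
            sides["right"] if sides["right"] is not None else np.nan,
            mean)


def measure_scp(volume: CanonicalVolume, plane: MidsagittalPlane,
                landmarks: LandmarkSet, posterior_offset_mm: float = 9.0,
                obliquity_deg: float = 0.0):
    """Superior cerebellar peduncle widths on a posterior coronal reformat.

    The measurement plane passes ``posterior_offset_mm`` behind the
    aqueduct, optionally tilted about the left-right axis; each peduncle's
    width is the narrowest perpendicular extent of the middle third of its
    course.  Returns ``(left, right, mean)`` in mm.
    """
    thr = landmarks.csf_threshold
    img0 = plane.slice2d
    ap = img0.e1
    si = img0.e2
    if obliquity_deg:
        c, s = np.cos(np.radians(obliquity_deg)), np.sin(np.radians(obliquity_deg))
        ap, si = c * ap + s * si, -s * ap + c * si
    origin = plane.origin - posterior_offset_mm * ap
    img = sample_plane(volume, origin, plane.normal, si,
                       (SCP_BOX_U[0] + 0.125, SCP_BOX_U[1] + 0.125),
                       (SCP_BOX_V[0] + 0.125, SCP_BOX_V[1] + 0.125), 0.25)
    tissue = img.data > thr
    labels, n = ndimage.label(tissue)
    sides = {"left": None, "right": None}
    for lab in range(1, n + 1):
        comp = labels == lab
        cu = img.u_min + np.argwhere(comp)[:, 0].mean() * img.step
        side = "left" if cu < 0 else "right"
        w = _component_width(img, comp, thr, ray_half_mm=8.0)
        if w is not None and (sides[side] is None or comp.sum() > 0):
            if sides[side] is None:
                sides[side] = w
    found = [v for v in sides.values() if v is not None]
    if not found:
        raise StageFailure("brainstem", "superior cerebellar peduncle not found on either side")
    mean = float(np.mean(found))
    return (sides["left"] if sides["left"] is not None else np.nan,
            sides["right"] if sides["right"] is not None else np.nan,
            mean)


def compute_mrpi(measures: BrainstemMeasures) -> float:
    """MRPI = (pons/midbrain area ratio) x (MCP/SCP width ratio)."""
    for v in (measures.pons_area_mm2, measures.midbrain_area_mm2,
              measures.mcp_mean_mm, measures.scp_mean_mm):
        if not (v > 0):
            raise ValueError("all four MRPI inputs must be positive")
    return (measures.pons_area_mm2 / measures.midbrain_area_mm2) * \
           (measures.mcp_mean_mm / measures.scp_mean_mm)
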