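"""Landmark detection, midsagittal-plane fitting and axial slab reformatting.

The midline geometry is anchored on three anatomical landmarks found by
combined threshold and connected-component analysis of the intensity-
normalized canonical volume:

* the maximal expansion of the Sylvian aqueduct — the narrow enclosed CSF
  channel dorsal to the brainstem, at the level of its widest cross-section;
* the corpus callosum — the bright midline arch immediately above the
  highest midline CSF cavity (body of the lateral ventricle);
* the upper brainstem — the tissue mass anterior-inferior to the aqueduct.

The midsagittal plane is then chosen deterministically as the candidate
plane (search over left-right offset and tilt, constrained to pass within
2 mm of the aqueduct) minimizing the left-right intensity asymmetry of the
brain.  A 35-slice, 1 mm reformatted axial slab parallel to the subcallosal
line exposes the third ventricle and frontal horns for the ventricular
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import StageFailure
from .preprocessing import CanonicalVolume
from .sampling import PlanarImage, csf_tissue_threshold, sample_plane

CONFIDENCE_THRESHOLD = 0.5
AQUEDUCT_MAX_CROSS_MM2 = 30.0   # wider midline CSF cavities are ventricles
AQUEDUCT_MIN_VOLUME_MM3 = 10.0
MIDLINE_TOL_MM = 3.0


@dataclass
class LandmarkSet:
    """World-mm coordinates of the three midline landmarks."""

    cc_point: np.ndarray
    brainstem_point: np.ndarray
    aqueduct_point: np.ndarray
    confidence: dict
    csf_threshold: float
    midline_x: float

    def __post_init__(self):
        pts = np.vstack([self.cc_point, self.brainstem_point, self.aqueduct_point])
        # non-collinearity: the three points must span a genuine plane
        area2 = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if area2 < 1e-6:
            raise StageFailure("landmarks", "landmarks are collinear")


@dataclass
class MidsagittalPlane:
    origin: np.ndarray
    normal: np.ndarray
    slice2d: PlanarImage
    asymmetry: float
    tilt_deg: tuple

    def __post_init__(self):
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("plane normal must be a unit vector")


@dataclass
class AxialSlab:
    """35 axial slices, 1 mm apart, parallel to the subcallosal line."""

    slices: list
    centers: np.ndarray
    stack_dir: np.ndarray
    subcallosal_direction: np.ndarray
    lr_axis: np.ndarray
    ap_axis: np.ndarray
    slice_mm: float
    csf_threshold: float

    def __post_init__(self):
        if len(self.slices) != 35:
            raise ValueError("axial slab must contain exactly 35 slices")


def enclosed_csf_components(data: np.ndarray, min_voxels: int = 4):
    """Label dark cavities fully enclosed by tissue (CSF spaces).

    Returns ``(labels, tissue_mask)`` or ``None`` if no tissue is present.
    Enclosure (fill-holes of the thresholded tissue mask) is what separates
    internal CSF from the dark background surrounding the head.
    """
    thr = csf_tissue_threshold(data)
    tissue = data > thr
    if not tissue.any():
        return None
    filled = ndimage.binary_fill_holes(tissue)
    csf = filled & ~tissue
    labels, n = ndimage.label(csf)
    if n:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        if small.size:
            labels[np.isin(labels, small)] = 0
            labels, _ = ndimage.label(labels > 0)
    return labels, tissue


def detect_landmarks(volume: CanonicalVolume) -> LandmarkSet:
    """Locate the three midline landmarks on a normalized canonical volume.

    Raises :class:`StageFailure` (stage ``"landmarks"``) naming the missing
    landmark when no candidate satisfies the geometric criteria, or when
    any landmark's confidence falls below 0.5.
    """
    data = volume.data
    thr = csf_tissue_threshold(data)
    comps = enclosed_csf_components(data)
    if comps is None:
        raise StageFailure("landmarks", "no tissue voxels above threshold")
    labels, tissue = comps
    nlab = labels.max()
    if nlab == 0:
        raise StageFailure("landmarks", "missing landmark: aqueduct (no enclosed CSF)")

    spacing = volume.spacing
    voxel_vol = float(np.prod(spacing))
    cross_area = float(spacing[0] * spacing[1])
    mid_i = ndimage.center_of_mass(tissue)[0]
    midline_x = float(volume.voxel_to_world([mid_i, 0, 0])[0][0])

    infos = []
    for lab in range(1, nlab + 1):
        vox = np.argwhere(labels == lab)
        cw = volume.voxel_to_world(vox.mean(axis=0))[0]
        per_z = np.bincount(vox[:, 2])
        infos.append(dict(label=lab, vox=vox, centroid=cw,
                          volume=len(vox) * voxel_vol,
                          max_cross=float(per_z.max()) * cross_area))

    midline = [c for c in infos if abs(c["centroid"][0] - midline_x) < MIDLINE_TOL_MM]
    aq_cands = [c for c in midline
                if c["max_cross"] <= AQUEDUCT_MAX_CROSS_MM2
                and c["volume"] >= AQUEDUCT_MIN_VOLUME_MM3]
    if not aq_cands:
        raise StageFailure("landmarks", "missing landmark: aqueduct")
    aq = min(aq_cands, key=lambda c: c["centroid"][2])
    # maximal expansion: z rows with the largest cross-section (middle of ties)
    zs = aq["vox"][:, 2]
    counts = np.bincount(zs)
    peak = counts.max()
    tie_rows = np.flatnonzero(counts == peak)
    sel = np.isin(zs, tie_rows)
    aqueduct_point = volume.voxel_to_world(aq["vox"][sel].mean(axis=0))[0]
    conf_aq = min(1.0, aq["volume"] / 20.0)

    cc_cands = [c for c in midline if c["label"] != aq["label"]
                and c["centroid"][2] > aqueduct_point[2] + 10.0]
    if not cc_cands:
        raise StageFailure("landmarks", "missing landmark: corpus callosum")
    gap = max(cc_cands, key=lambda c: c["centroid"][2])
    gap_top = volume.voxel_to_world([0, 0, gap["vox"][:, 2].max()])[0][2]
    cc_point = np.array([midline_x, gap["centroid"][1], gap_top + 1.0])
    conf_cc = min(1.0, gap["volume"] / 50.0)

    # upper brainstem: tissue centroid in a box anterior-inferior to the aqueduct
    lo = np.array([midline_x - 8.0, aqueduct_point[1] - 2.5, aqueduct_point[2] - 22.0])
    hi = np.array([midline_x + 8.0, aqueduct_point[1] + 18.0, aqueduct_point[2] + 4.0])
    ilo = np.maximum(np.ceil(volume.world_to_voxel(lo)[0]).astype(int), 0)
    ihi = np.minimum(np.floor(volume.world_to_voxel(hi)[0]).astype(int) + 1,
                     np.asarray(volume.shape))
    box = tissue[ilo[0]:ihi[0], ilo[1]:ihi[1], ilo[2]:ihi[2]]
    if box.size == 0 or not box.any():
        raise StageFailure("landmarks", "missing landmark: upper brainstem")
    frac = float(box.mean())
    bs_local = np.argwhere(box).mean(axis=0) + ilo
    brainstem_point = volume.voxel_to_world(bs_local)[0]
    conf_bs = min(1.0, frac / 0.3)

    confidence = {"aqueduct": conf_aq, "corpus_callosum": conf_cc,
                  "brainstem": conf_bs}
    worst = min(confidence, key=confidence.get)
    if confidence[worst] < CONFIDENCE_THRESHOLD:
        raise StageFailure("landmarks", f"low confidence landmark: {worst}")
    return LandmarkSet(cc_point=cc_point, brainstem_point=brainstem_point,
                       aqueduct_point=aqueduct_point, confidence=confidence,
                       csf_threshold=thr, midline_x=midline_x)


def _candidate_normal(yaw_deg: float, roll_deg: float) -> np.ndarray:
    a, b = np.radians(yaw_deg), np.radians(roll_deg)
    # rotate +x by yaw about z then roll about y
    n = np.array([np.cos(a), np.sin(a), 0.0])
    rb = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    return rb @ n


def fit_midsagittal(volume: CanonicalVolume, landmarks: LandmarkSet,
                    max_tilt_deg: float = 10.0, max_offset_mm: float = 2.0,
                    slice_step_mm: float = 0.25) -> MidsagittalPlane:
    """Deterministic asymmetry-minimizing midsagittal plane search.

    Candidate planes pass within ``max_offset_mm`` of the aqueduct point
    (offsets stepped at 0.25 mm) with tilt up to ``max_tilt_deg`` about the
    superior and anterior axes; the plane minimizing mean left-right
    intensity asymmetry is returned, ties broken by proximity to the
    aqueduct and then by smallest tilt.
    """
    data = volume.data
    tissue = data > landmarks.csf_threshold
    vox = np.argwhere(tissue)
    if len(vox) == 0:
        raise StageFailure("midsagittal", "empty candidate set: no tissue")
    stride = max(1, len(vox) // 8000)
    vox = vox[::stride]
    pts = volume.voxel_to_world(vox)
    vals = data[tuple(vox.T)]
    aq = landmarks.aqueduct_point

    def score(yaw, roll, off):
        n = _candidate_normal(yaw, roll)
        p0 = aq + off * n
        d = (pts - p0) @ n
        mirror = pts - 2.0 * d[:, None] * n
        ok = volume.contains_world(mirror)
        if not ok.any():
            return None
        mv = volume.sample_world(mirror[ok])
        return float(np.mean(np.abs(vals[ok] - mv)))

    offsets = np.arange(-max_offset_mm, max_offset_mm + 1e-9, 0.25)
    tilts = np.arange(-max_tilt_deg, max_tilt_deg + 1e-9, 1.0)

    def scan(axis_vals, current, axis):
        best = None
        for v in axis_vals:
            yaw, roll, off = current
            cand = {"yaw": (v, roll, off), "roll": (yaw, v, off),
                    "off": (yaw, roll, v)}[axis]
            s = score(*cand)
            if s is None:
                continue
            key = (round(s, 12), abs(cand[2]), abs(cand[0]) + abs(cand[1]))
            if best is None or key < best[0]:
                best = (key, cand)
        if best is None:
            raise StageFailure("midsagittal", "empty candidate set")
        return best[1]

    cur = (0.0, 0.0, 0.0)
    cur = scan(offsets, cur, "off")
    cur = scan(tilts, cur, "yaw")
    cur = scan(tilts, cur, "roll")
    cur = scan(offsets, cur, "off")
    fine = np.arange(-1.0, 1.0 + 1e-9, 0.25)
    cur = scan(cur[0] + fine, cur, "yaw")
    cur = scan(cur[1] + fine, cur, "roll")

    yaw, roll, off = cur
    n = _candidate_normal(yaw, roll)
    p0 = aq + off * n
    final = score(yaw, roll, off)
    e1 = np.array([0.0, 1.0, 0.0]) - n[1] * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    # half-step grid offset keeps sample points off voxel-boundary knife edges
    h = slice_step_mm / 2.0
    slice2d = sample_plane(volume, p0, e1, e2, (-50.0 + h, 50.0 + h),
                           (-45.0 + h, 50.0 + h), slice_step_mm)
    return MidsagittalPlane(origin=p0, normal=n, slice2d=slice2d,
                            asymmetry=final, tilt_deg=(yaw, roll))


def _subcallosal_line(plane: MidsagittalPlane, csf_threshold: float):
    """Least-squares line under the corpus callosum on the midsagittal slice.

    The inferior callosal boundary is taken as the upper boundary of the
    highest midline CSF cavity (the ventricle body beneath the callosal
    arch); returns ``(v = a + b*u)`` coefficients in slice coordinates.
    """
    img = plane.slice2d
    tissue = img.data > csf_threshold
    filled = ndimage.binary_fill_holes(tissue)
    csf = filled & ~tissue
    labels, n = ndimage.label(csf)
    if n == 0:
        raise StageFailure("slab", "no enclosed CSF on midsagittal slice")
    best, best_v = None, -np.inf
    for lab in range(1, n + 1):
        px = np.argwhere(labels == lab)
        if len(px) * img.pixel_area < 20.0:
            continue
        cv = img.v_min + px[:, 1].mean() * img.step
        if cv > best_v:
            best, best_v = px, cv
    if best is None:
        raise StageFailure("slab", "no subcallosal CSF gap found")
    # topmost pixel per column
    us, tops = [], []
    for i in np.unique(best[:, 0]):
        j = best[best[:, 0] == i, 1].max()
        u, v = img.uv_of_index(i, j)
        us.append(u)
        tops.append(v + img.step / 2.0)  # boundary lies half a pixel above the center
    us, tops = np.asarray(us), np.asarray(tops)
    if len(us) < 3:
        raise StageFailure("slab", "subcallosal boundary too short to fit")
    b, a = np.polyfit(us, tops, 1)
    if abs(b) > 0.5:
        raise StageFailure("slab", "implausible subcallosal line slope")
    return a, b


def build_axial_slab(volume: CanonicalVolume, landmarks: LandmarkSet,
                     plane: MidsagittalPlane, n_slices: int = 35,
                     slice_mm: float = 1.0, extent_mm: float = 50.0,
                     step_mm: float = 0.5) -> AxialSlab:
    """Reformat 35 axial 1 mm slices parallel to the subcallosal line.

    The first slice is tangent to the subcallosal line; the stack extends
    inferiorly, covering the third ventricle and frontal horns in canonical
    space.  Raises :class:`StageFailure` (stage ``"slab"``) when the slab
    leaves the volume.
    """
    a, b = _subcallosal_line(plane, landmarks.csf_threshold)
    img = plane.slice2d
    d = img.e1 + b * img.e2
    d /= np.linalg.norm(d)
    anchor = img.origin + a * img.e2
    s = np.cross(d, plane.normal)
    s /= np.linalg.norm(s)
    if s[2] > 0:  # stack must extend inferiorly
        s = -s
    centers = anchor + np.arange(n_slices)[:, None] * slice_mm * s
    inside = volume.contains_world(centers)
    if not inside.all():
        raise StageFailure("slab", "axial slab extends outside the volume")
    h = step_mm / 2.0
    slices = [sample_plane(volume, c, plane.normal, d,
                           (-extent_mm + h, extent_mm + h),
                           (-extent_mm + h, extent_mm + h), step_mm)
              for c in centers]
    return AxialSlab(slices=slices, centers=centers, stack_dir=s,
                     subcallosal_direction=d, lr_axis=plane.normal, ap_axis=d,
                     slice_mm=slice_mm, csf_threshold=landmarks.csf_threshold)
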