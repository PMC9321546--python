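"""Third-ventricle and frontal-horn width measurement on the axial slab.

The third ventricle (3V) is the slit-like midline CSF cavity; its width is
measured with a two-pass protocol: a screening pass takes two left-right
linear measurements per slice (at 1/3 and 2/3 of the cavity's
anteroposterior extent) to find the slice with the largest width, then six
equally spaced measurements over the middle 80% of the extent on that
slice are averaged.  The frontal-horn (FH) span is the left-right distance
between the outermost lateral borders of the paired anterior horns,
maximized over slices.  All linear measures use sub-pixel
threshold-crossing interpolation; ties across slices resolve to the
inferior-most slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import StageFailure
from .midsagittal import AxialSlab
from .sampling import run_bounds

MIDLINE_TOL_MM = 3.0
MIN_COMPONENT_MM2 = 4.0


@dataclass
class SliceCSF:
    """Classified CSF components of one axial slab slice."""

    v3_mask: np.ndarray | None
    fh_left: list
    fh_right: list


@dataclass
class SlabSegmentation:
    per_slice: list
    threshold: float

    def v3_slices(self):
        return [k for k, s in enumerate(self.per_slice) if s.v3_mask is not None]

    def fh_slices(self):
        return [k for k, s in enumerate(self.per_slice)
                if s.fh_left and s.fh_right]


@dataclass
class VentricleMeasures:
    v3_width_mm: float
    v3_slice_index: int
    v3_six_measures: tuple
    fh_width_mm: float
    fh_slice_index: int

    def __post_init__(self):
        if abs(self.v3_width_mm - float(np.mean(self.v3_six_measures))) > 1e-9:
            raise ValueError("v3 width must equal the mean of the six measures")
        if not (0 < self.v3_width_mm < self.fh_width_mm):
            raise StageFailure("ventricles",
                               "implausible widths: 3V must be smaller than FH span")
        for k in (self.v3_slice_index, self.fh_slice_index):
            if not (0 <= k <= 34):
                raise ValueError("slice index outside the 35-slice slab")


def segment_csf_slab(slab: AxialSlab) -> SlabSegmentation:
    """Per-slice CSF masks, classified into 3V and frontal-horn candidates.

    CSF is the set of dark cavities enclosed by tissue on each slice; the
    midline component is the 3V candidate and off-midline components are
    horn candidates, split by side.  Raises :class:`StageFailure`
    (stage ``"ventricles"``) when no slice contains CSF.
    """
    thr = slab.csf_threshold
    out = []
    any_csf = False
    for img in slab.slices:
        tissue = img.data > thr
        if not tissue.any():
            out.append(SliceCSF(None, [], []))
            continue
        filled = ndimage.binary_fill_holes(tissue)
        csf = filled & ~tissue
        labels, n = ndimage.label(csf)
        v3_mask, fhl, fhr = None, [], []
        v3_size = 0
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() * img.pixel_area < MIN_COMPONENT_MM2:
                continue
            any_csf = True
            px = np.argwhere(comp)
            cu = img.u_min + px[:, 0].mean() * img.step
            umin = img.u_min + px[:, 0].min() * img.step
            umax = img.u_min + px[:, 0].max() * img.step
            if abs(cu) < MIDLINE_TOL_MM and umin < 0 < umax:
                if comp.sum() > v3_size:
                    v3_mask, v3_size = comp, comp.sum()
            elif cu <= -MIDLINE_TOL_MM:
                fhl.append(comp)
            elif cu >= MIDLINE_TOL_MM:
                fhr.append(comp)
        out.append(SliceCSF(v3_mask, fhl, fhr))
    if not any_csf:
        raise StageFailure("ventricles", "no CSF found in any slab slice")
    return SlabSegmentation(per_slice=out, threshold=thr)


def _lr_width_at(img, comp, thr, v_pos):
    """Sub-pixel left-right CSF width of a component at AP position v_pos."""
    px = np.argwhere(comp)
    vs = img.v_min + px[:, 1] * img.step
    near = np.abs(vs - v_pos) <= img.step
    if not near.any():
        return None
    u_center = img.u_min + px[near, 0].mean() * img.step
    ss = np.arange(-30.0, 30.0 + 1e-9, 0.05)
    vals = img.sample_uv(u_center + ss, np.full_like(ss, v_pos))
    run = run_bounds(ss, vals, thr, 0.0, above=False)
    if run is None:
        return None
    return run[1] - run[0]


def _comp_ap_extent(img, comp):
    px = np.argwhere(comp)
    vs = img.v_min + px[:, 1] * img.step
    return float(vs.min()), float(vs.max())


def select_v3_slice(slab: AxialSlab, seg: SlabSegmentation) -> int:
    """Screening pass: the slab slice with the largest 3V width.

    Two linear width measurements per candidate slice (at 1/3 and 2/3 of
    the anteroposterior extent); the slice maximizing the larger of the two
    wins, ties resolving to the inferior-most slice.
    """
    candidates = seg.v3_slices()
    if not candidates:
        raise StageFailure("ventricles", "no slice shows the third ventricle")
    best_k, best_w = None, -np.inf
    for k in candidates:
        img = slab.slices[k]
        comp = seg.per_slice[k].v3_mask
        v0, v1 = _comp_ap_extent(img, comp)
        widths = []
        for frac in (1.0 / 3.0, 2.0 / 3.0):
            w = _lr_width_at(img, comp, seg.threshold, v0 + frac * (v1 - v0))
            if w is not None:
                widths.append(w)
        if not widths:
            continue
        w = max(widths)
        if w >= best_w:  # later (more inferior) slices win ties
            best_k, best_w = k, w
    if best_k is None:
        raise StageFailure("ventricles", "no measurable third-ventricle slice")
    return best_k


def measure_v3_width(slab: AxialSlab, seg: SlabSegmentation,
                     slice_index: int):
    """Six-measure pass on the selected slice.

    Six left-right border-to-border distances at equally spaced positions
    spanning the middle 80% of the 3V's anteroposterior extent; returns
    ``(mean_width_mm, six_measures)``.
    """
    s = seg.per_slice[slice_index]
    if s.v3_mask is None:
        raise StageFailure("ventricles", "selected slice lost the third ventricle")
    img = slab.slices[slice_index]
    v0, v1 = _comp_ap_extent(img, s.v3_mask)
    fracs = 0.1 + 0.8 * np.arange(6) / 5.0
    six = []
    for f in fracs:
        w = _lr_width_at(img, s.v3_mask, seg.threshold, v0 + f * (v1 - v0))
        if w is None:
            raise StageFailure("ventricles", "fewer than six valid 3V cross-sections")
        six.append(float(w))
    return float(np.mean(six)), tuple(six)


def _outer_crossing(img, comp, thr, side: str):
    """Sub-pixel outermost lateral border of a horn component.

    Scans every row on which the component reaches its extreme lateral
    pixel (within one pixel) and returns the outermost threshold crossing,
    so partial-volume corner rows cannot bias the span inward.
    """
    px = np.argwhere(comp)
    extreme = px[:, 0].min() if side == "left" else px[:, 0].max()
    rows = np.unique(px[np.abs(px[:, 0] - extreme) <= 1, 1])
    ss = np.arange(-12.0, 12.0 + 1e-9, 0.05)
    u = img.u_min + extreme * img.step
    out = None
    for j in rows:
        v = img.v_min + j * img.step
        vals = img.sample_uv(u + ss, np.full_like(ss, v))
        run = run_bounds(ss, vals, thr, 0.0, above=False)
        if run is None:
            continue
        x = u + (run[0] if side == "left" else run[1])
        if out is None or (x < out if side == "left" else x > out):
            out = x
    return out


def measure_fh_width(slab: AxialSlab, seg: SlabSegmentation):
    """Maximal left-right frontal-horn span over the slab.

    Per slice, the distance between the outer lateral borders of the paired
    horn components; the maximum over slices is returned with its slice
    index (ties to the inferior-most slice).
    """
    best_k, best_w = None, -np.inf
    for k in seg.fh_slices():
        img = slab.slices[k]
        s = seg.per_slice[k]
        lefts = [_outer_crossing(img, c, seg.threshold, "left") for c in s.fh_left]
        rights = [_outer_crossing(img, c, seg.threshold, "right") for c in s.fh_right]
        lefts = [x for x in lefts if x is not None]
        rights = [x for x in rights if x is not None]
        if not lefts or not rights:
            continue
        w = max(rights) - min(lefts)
        if w >= best_w:
            best_k, best_w = k, w
    if best_k is None:
        raise StageFailure("ventricles", "frontal horns absent in all slices")
    return float(best_w), best_k


def measure_ventricles(slab: AxialSlab) -> VentricleMeasures:
    """Full ventricular protocol on a slab: segmentation, both widths."""
    seg = segment_csf_slab(slab)
    k3 = select_v3_slice(slab, seg)
    v3, six = measure_v3_width(slab, seg, k3)
    fh, kf = measure_fh_width(slab, seg)
    return VentricleMeasures(v3_width_mm=v3, v3_slice_index=k3,
                             v3_six_measures=six, fh_width_mm=fh,
                             fh_slice_index=kf)
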