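"""Synthetic T1-like brain phantoms with fully known geometry.

The measurement pipeline is validated on schematic 3D phantoms rather than
patient scans: every structure the index depends on — the midbrain and pons
midsagittal profiles, middle and superior cerebellar peduncle bars, the
slit-like third ventricle, the paired frontal horns, the Sylvian aqueduct
and a subcallosal CSF gap beneath the corpus callosum — is an axis-aligned
box (optionally rotated rigidly as a whole) whose dimensions are requested
in millimetres, snapped to voxel boundaries, and recorded as ground truth.

Contrast is two-class T1-like: brain tissue bright (0.8), CSF dark (0.1),
background 0, plus optional additive Gaussian noise.  Because every
operator downstream is geometric (thresholds, connected components, linear
and area measurements), geometric fidelity is what matters; no MR physics
is simulated.

The module also simulates scalar cohorts (per-group Gaussian MRPI 2.0 and
age distributions, truncated at zero) for exercising the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import ConstructionError
from .volume import VolumeImage, centered_affine

# ---------------------------------------------------------------------------
# Intensity model
TISSUE = 0.8
CSF = 0.1
BACKGROUND = 0.0

# Canonical layout constants (mm, world origin at volume center).
VOLUME_MM = 110.0           # cube side
BRAINSTEM_HALF_X = 10.0
PONS_Z = (-38.0, -18.0)     # junction boundary at z = -18
MIDBRAIN_Z = (-18.0, -9.0)
BRAINSTEM_BACK_Y = -20.0    # pons posterior face
MIDBRAIN_BACK_Y = -16.0
NOTCH_Z = (-20.0, -16.0)    # pontomesencephalic notch, centered on junction
NOTCH_DEPTH = 3.0           # anterior bite depth relative to midbrain front
AQUEDUCT = dict(x=1.2, y=(-13.5, -11.0), z=(-16.0, -11.0))
AQUEDUCT_BULGE = dict(x=2.0, y=(-14.0, -10.5), z=(-14.5, -12.5))
MCP_X = (6.0, 20.0)         # per-side lateral extent
MCP_Y = (-18.0, 2.0)
MCP_Z_BOTTOM = -30.0        # bar thickness (the measured width) extends upward
SCP_CENTER_X = 6.0          # per-side bar center; thickness is the measured width
SCP_Y = (-26.0, -16.0)
SCP_Z = (-20.0, -6.0)
CEREBRUM = dict(x=45.0, y=45.0, z=(-4.0, 40.0))
V3_Y = (-15.0, 10.0)
V3_Z_WIDE = (-2.0, 6.0)     # full-width band (the widest axial level)
V3_Z_NARROW = (6.0, 18.0)   # tapers to 60% width superiorly
V3_TAPER = 0.6
FH_Y = (14.0, 34.0)
FH_Z = (-2.0, 14.0)
FH_THICKNESS = 8.0          # per-horn lateral thickness
SUBCALLOSAL = dict(x=1.25, y=(-20.0, 25.0), z=(24.0, 28.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Requested phantom geometry; all dimensions in mm.

    Defaults are in the magnitude range reported for automated measurements
    in parkinsonian cohorts (midbrain ~100 mm2, pons ~500 mm2, MCP ~9 mm,
    SCP ~3 mm, third ventricle 4-9 mm, frontal horn span 30-42 mm).
    """

    midbrain_area_mm2: float = 105.0
    pons_area_mm2: float = 520.0
    mcp_width_mm: float = 9.0
    scp_width_mm: float = 3.0
    v3_width_mm: float = 5.2
    fh_width_mm: float = 36.0
    voxel_mm: float = 1.0
    tilt_deg: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("midbrain_area_mm2", "pons_area_mm2", "mcp_width_mm",
                     "scp_width_mm", "v3_width_mm", "fh_width_mm"):
            if getattr(self, name) <= 0:
                raise ConstructionError(f"{name} must be strictly positive")
        if not (0.4 < self.voxel_mm <= 2.0):
            raise ConstructionError("voxel_mm must lie in (0.4, 2.0]")
        if self.v3_width_mm >= self.fh_width_mm:
            raise ConstructionError("v3_width_mm must be smaller than fh_width_mm")
        if self.noise_sd < 0:
            raise ConstructionError("noise_sd must be non-negative")
        if self.v3_width_mm < 3.2:
            raise ConstructionError(
                "v3_width_mm below 3.2 mm collides with the subcallosal gap width")
        if not (19.0 < self.fh_width_mm < 86.0):
            raise ConstructionError(
                "fh_width_mm outside (19, 86) mm: horns collide or leave the cerebrum")
        if self.mcp_width_mm > 11.0:
            raise ConstructionError("mcp_width_mm above 11 mm collides with the cerebrum")
        if self.scp_width_mm > 7.0:
            raise ConstructionError("scp_width_mm above 7 mm collides with the midline")
        md = self._midbrain_depth()
        if not (8.0 <= md <= 20.0):
            raise ConstructionError(
                "midbrain_area_mm2 yields an anteroposterior depth outside [5, 20] mm")
        pd_ = self._pons_depth()
        if pd_ - md - 1.0 < 1.0:
            raise ConstructionError(
                "pons_area_mm2 too small: pons must bulge anterior to the junction notch")
        if BRAINSTEM_BACK_Y + pd_ > 13.0:
            raise ConstructionError("pons_area_mm2 yields an anterior face beyond bounds")
        if max(abs(a) for a in self.tilt_deg) > 12.0:
            raise ConstructionError("tilt_deg beyond 12 degrees pushes structures out of bounds")

    # Profile depths compensate the in-plane aqueduct carve and the notch
    # bite so that realized midplane areas track the requested areas.
    def _aqueduct_inplane_area(self) -> float:
        a = (AQUEDUCT["y"][1] - AQUEDUCT["y"][0]) * (AQUEDUCT["z"][1] - AQUEDUCT["z"][0])
        extra = ((AQUEDUCT_BULGE["y"][1] - AQUEDUCT_BULGE["y"][0])
                 - (AQUEDUCT["y"][1] - AQUEDUCT["y"][0])) * \
                (AQUEDUCT_BULGE["z"][1] - AQUEDUCT_BULGE["z"][0])
        return a + extra

    def _midbrain_depth(self) -> float:
        h = MIDBRAIN_Z[1] - MIDBRAIN_Z[0]
        notch_loss = NOTCH_DEPTH * (MIDBRAIN_Z[0] - NOTCH_Z[0])
        return (self.midbrain_area_mm2 + self._aqueduct_inplane_area() + notch_loss) / h

    def _pons_depth(self) -> float:
        # pons front f satisfies: h*(f - back) - (f - notch_front)*notch_rows = area
        h = PONS_Z[1] - PONS_Z[0]
        md = self._midbrain_depth()
        notch_front = MIDBRAIN_BACK_Y + md - NOTCH_DEPTH
        rows = PONS_Z[1] - NOTCH_Z[0]
        # depth d: 20*d - (back + d - notch_front)*rows = area
        return (self.pons_area_mm2 - rows * (notch_front - BRAINSTEM_BACK_Y)) / (h - rows)


@dataclass
class GroundTruth:
    """Realized phantom geometry as rasterized on the discrete grid.

    Dimensions are counted from the canonical-frame voxelization (snapping
    box faces to voxel boundaries), so they are pose-invariant by
    construction.  Plane and landmark fields are expressed in world mm of
    the (possibly tilted) output volume.
    """

    midbrain_area_mm2: float
    pons_area_mm2: float
    mcp_width_mm: float
    scp_width_mm: float
    v3_width_mm: float
    fh_width_mm: float
    msp_origin: np.ndarray
    msp_normal: np.ndarray
    subcallosal_point: np.ndarray
    subcallosal_dir: np.ndarray
    aqueduct_point: np.ndarray
    junction_z: float
    v3_widest_z: tuple
    rotation: np.ndarray
    spec: PhantomSpec
    boxes: dict = field(repr=False, default_factory=dict)

    @property
    def mrpi(self) -> float:
        return (self.pons_area_mm2 / self.midbrain_area_mm2) * \
               (self.mcp_width_mm / self.scp_width_mm)

    @property
    def mrpi2(self) -> float:
        return self.mrpi * self.v3_width_mm / self.fh_width_mm

    def contains(self, structure: str, points_world: np.ndarray) -> np.ndarray:
        """Membership of world-space points in a named structure (e.g. 'v3')."""
        pts = np.atleast_2d(points_world) @ self.rotation  # R^-1 p, rotation orthonormal
        inside = np.zeros(len(pts), dtype=bool)
        for lo, hi in self.boxes[structure]:
            inside |= np.all((pts >= lo) & (pts < hi), axis=1)
        return inside

    def to_json_dict(self) -> dict:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items() if k not in ("boxes", "spec")}
        d["rotation"] = self.rotation.tolist()
        d["spec"] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in self.spec.__dict__.items()}
        d["mrpi"] = self.mrpi
        d["mrpi2"] = self.mrpi2
        return d


def _snap(value: float, voxel: float, n: int) -> float:
    """Snap a world coordinate to the nearest voxel boundary of the centered grid."""
    return (round(value / voxel + n / 2.0) - n / 2.0) * voxel


def _boxes(spec: PhantomSpec, voxel: float, n: int):
    """Snapped axis-aligned boxes for every structure, plus realized dims."""
    s = lambda v: _snap(v, voxel, n)
    md = spec._midbrain_depth()
    pdep = spec._pons_depth()
    mb_front = MIDBRAIN_BACK_Y + md
    pons_front = BRAINSTEM_BACK_Y + pdep
    notch_front = mb_front - NOTCH_DEPTH

    def width_vox(w):
        return max(1, round(w / voxel)) * voxel

    # width-preserving snapping: snap the low edge to a voxel boundary and
    # carry the width rounded to whole voxels, so realized dimensions stay
    # within half a voxel of the request.
    v3_lo = s(-spec.v3_width_mm / 2.0)
    v3_hi = v3_lo + width_vox(spec.v3_width_mm)
    v3n_lo = s(-spec.v3_width_mm * V3_TAPER / 2.0)
    v3n_hi = v3n_lo + width_vox(spec.v3_width_mm * V3_TAPER)
    fh_lo = s(-spec.fh_width_mm / 2.0)
    fh_hi = fh_lo + width_vox(spec.fh_width_mm)
    horn_w = width_vox(FH_THICKNESS)
    mcp_bot = s(MCP_Z_BOTTOM)
    mcp_top = mcp_bot + width_vox(spec.mcp_width_mm)
    scp_lo = s(SCP_CENTER_X - spec.scp_width_mm / 2.0)
    scp_hi = scp_lo + width_vox(spec.scp_width_mm)

    def box(xlo, xhi, ylo, yhi, zlo, zhi):
        return (np.array([s(xlo), s(ylo), s(zlo)]), np.array([s(xhi), s(yhi), s(zhi)]))

    tissue = {
        "pons": [box(-BRAINSTEM_HALF_X, BRAINSTEM_HALF_X,
                     BRAINSTEM_BACK_Y, pons_front, *PONS_Z)],
        "midbrain": [box(-BRAINSTEM_HALF_X, BRAINSTEM_HALF_X,
                         MIDBRAIN_BACK_Y, mb_front, *MIDBRAIN_Z)],
        "mcp": [(np.array([s(MCP_X[0]), s(MCP_Y[0]), mcp_bot]),
                 np.array([s(MCP_X[1]), s(MCP_Y[1]), mcp_top])),
                (np.array([s(-MCP_X[1]), s(MCP_Y[0]), mcp_bot]),
                 np.array([s(-MCP_X[0]), s(MCP_Y[1]), mcp_top]))],
        "scp": [(np.array([scp_lo, s(SCP_Y[0]), s(SCP_Z[0])]),
                 np.array([scp_hi, s(SCP_Y[1]), s(SCP_Z[1])])),
                (np.array([-scp_hi, s(SCP_Y[0]), s(SCP_Z[0])]),
                 np.array([-scp_lo, s(SCP_Y[1]), s(SCP_Z[1])]))],
        "cerebrum": [box(-CEREBRUM["x"], CEREBRUM["x"], -CEREBRUM["y"], CEREBRUM["y"],
                         *CEREBRUM["z"])],
    }
    carve = {
        "notch": [box(-BRAINSTEM_HALF_X, BRAINSTEM_HALF_X,
                      notch_front, pons_front + 1.0, *NOTCH_Z)],
        # the bulge must stay strictly interior to the midbrain: clamp its
        # posterior face one voxel in front of the midbrain's back face and
        # its top one voxel below the midbrain top, whatever the snapping did
        "aqueduct": [box(-AQUEDUCT["x"], AQUEDUCT["x"], AQUEDUCT["y"][0],
                         AQUEDUCT["y"][1],
                         AQUEDUCT["z"][0], min(s(AQUEDUCT["z"][1]),
                                               s(MIDBRAIN_Z[1]) - voxel)),
                     (np.array([s(-AQUEDUCT_BULGE["x"]),
                                max(s(AQUEDUCT_BULGE["y"][0]),
                                    s(MIDBRAIN_BACK_Y) + voxel),
                                s(AQUEDUCT_BULGE["z"][0])]),
                      np.array([s(AQUEDUCT_BULGE["x"]), s(AQUEDUCT_BULGE["y"][1]),
                                s(AQUEDUCT_BULGE["z"][1])]))],
        "v3": [(np.array([v3_lo, s(V3_Y[0]), s(V3_Z_WIDE[0])]),
                np.array([v3_hi, s(V3_Y[1]), s(V3_Z_WIDE[1])])),
               (np.array([v3n_lo, s(V3_Y[0]), s(V3_Z_NARROW[0])]),
                np.array([v3n_hi, s(V3_Y[1]), s(V3_Z_NARROW[1])]))],
        "fh": [(np.array([fh_hi - horn_w, s(FH_Y[0]), s(FH_Z[0])]),
                np.array([fh_hi, s(FH_Y[1]), s(FH_Z[1])])),
               (np.array([fh_lo, s(FH_Y[0]), s(FH_Z[0])]),
                np.array([fh_lo + horn_w, s(FH_Y[1]), s(FH_Z[1])]))],
        "subcallosal": [box(-SUBCALLOSAL["x"], SUBCALLOSAL["x"],
                            *SUBCALLOSAL["y"], *SUBCALLOSAL["z"])],
    }
    realized = {
        "v3_width_mm": v3_hi - v3_lo,
        "fh_width_mm": fh_hi - fh_lo,
        "mcp_width_mm": mcp_top - mcp_bot,
        "scp_width_mm": scp_hi - scp_lo,
    }
    return tissue, carve, realized


def _profile_areas(tissue, carve, pixel=0.25):
    """Brute-force midsagittal profile areas (mm2) of the carved brainstem.

    Counted on a fine 2D grid of the snapped canonical geometry at x = 0,
    independent of the measurement pipeline.
    """
    ys = np.arange(-32.0, 16.0, pixel) + pixel / 2.0
    zs = np.arange(-42.0, -5.0, pixel) + pixel / 2.0
    Y, Z = np.meshgrid(ys, zs, indexing="ij")

    def in2d(boxlist):
        m = np.zeros(Y.shape, dtype=bool)
        for lo, hi in boxlist:
            m |= (Y >= lo[1]) & (Y < hi[1]) & (Z >= lo[2]) & (Z < hi[2])
        return m

    removed = in2d(carve["notch"]) | in2d(carve["aqueduct"])
    pons = in2d(tissue["pons"]) & ~removed
    midbrain = in2d(tissue["midbrain"]) & ~removed
    return float(midbrain.sum()) * pixel ** 2, float(pons.sum()) * pixel ** 2


def generate_phantom(spec: PhantomSpec):
    """Rasterize a phantom volume and its ground truth.

    Returns ``(VolumeImage, GroundTruth)``.  Deterministic given
    ``spec.seed``; raises :class:`ConstructionError` on invalid geometry.
    """
    spec.validate()
    voxel = float(spec.voxel_mm)
    n = int(round(VOLUME_MM / voxel))
    tissue, carve, realized = _boxes(spec, voxel, n)

    rot = Rotation.from_euler("xyz", spec.tilt_deg, degrees=True).as_matrix()
    affine = centered_affine((n, n, n), voxel)
    # Evaluate canonical geometry at back-rotated voxel centers.
    idx = (np.arange(n) - (n - 1) / 2.0) * voxel
    X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    if any(a != 0 for a in spec.tilt_deg):
        pts = pts @ rot  # p_canonical = R^T p_world, as row vectors p @ R
    xs, ys, zs = pts[:, 0], pts[:, 1], pts[:, 2]

    def member(boxlist):
        m = np.zeros(len(pts), dtype=bool)
        for lo, hi in boxlist:
            m |= ((xs >= lo[0]) & (xs < hi[0]) & (ys >= lo[1]) & (ys < hi[1])
                  & (zs >= lo[2]) & (zs < hi[2]))
        return m

    vol = np.full(len(pts), BACKGROUND, dtype=np.float32)
    tissue_mask = np.zeros(len(pts), dtype=bool)
    for name in ("pons", "midbrain", "mcp", "scp", "cerebrum"):
        tissue_mask |= member(tissue[name])
    vol[tissue_mask] = TISSUE
    for name in ("notch",):
        vol[tissue_mask & member(carve[name])] = BACKGROUND
    for name in ("aqueduct", "v3", "fh", "subcallosal"):
        vol[tissue_mask & member(carve[name])] = CSF
    vol = vol.reshape(n, n, n)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape).astype(np.float32)
        vol = np.clip(vol, 0.0, None)

    mb_area, pons_area = _profile_areas(tissue, carve)
    s = lambda v: _snap(v, voxel, n)
    aq_z = 0.5 * (s(AQUEDUCT_BULGE["z"][0]) + s(AQUEDUCT_BULGE["z"][1]))
    aq_y = 0.5 * (s(AQUEDUCT["y"][0]) + s(AQUEDUCT["y"][1]))
    gt = GroundTruth(
        midbrain_area_mm2=mb_area,
        pons_area_mm2=pons_area,
        v3_width_mm=realized["v3_width_mm"],
        fh_width_mm=realized["fh_width_mm"],
        mcp_width_mm=realized["mcp_width_mm"],
        scp_width_mm=realized["scp_width_mm"],
        msp_origin=rot @ np.zeros(3),
        msp_normal=rot @ np.array([1.0, 0.0, 0.0]),
        subcallosal_point=rot @ np.array([0.0, 0.0, s(SUBCALLOSAL["z"][1])]),
        subcallosal_dir=rot @ np.array([0.0, 1.0, 0.0]),
        aqueduct_point=rot @ np.array([0.0, aq_y, aq_z]),
        junction_z=s(PONS_Z[1]),
        v3_widest_z=(s(V3_Z_WIDE[0]), s(V3_Z_WIDE[1])),
        rotation=rot,
        spec=spec,
        boxes={**carve, **{k: v for k, v in tissue.items()}},
    )
    image = VolumeImage(vol, affine, meta={"phantom": True, "field_strength": "3T"})
    return image, gt


# ---------------------------------------------------------------------------
# Corruption modes emulating acquisition failures

CORRUPT_MODES = ("ghosting", "landmark_dropout", "intensity_clip")


def corrupt_phantom(volume: VolumeImage, mode: str, seed: int = 0,
                    amplitude: float = 0.5, clip_quantile: float = 0.01) -> VolumeImage:
    """Return a degraded copy of a volume.

    ``ghosting`` superimposes shifted replicas of the image (motion-like);
    ``landmark_dropout`` erases the aqueduct region so landmark detection
    must fail; ``intensity_clip`` saturates everything above the stated
    quantile of nonzero voxels (default the 1st percentile, i.e. down to
    the CSF floor), destroying internal contrast.  All modes are
    deterministic given ``seed``.
    """
    if mode not in CORRUPT_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    out = volume.copy()
    rng = np.random.default_rng(seed)
    if mode == "ghosting":
        shift = max(1, int(round(15.0 / volume.spacing[1])))
        ghost = np.roll(out.data, shift, axis=1) + np.roll(out.data, -shift, axis=1)
        out.data = out.data + np.float32(amplitude) * ghost.astype(np.float32)
    elif mode == "landmark_dropout":
        cross_area = float(volume.spacing[0] * volume.spacing[1])
        out.data = _erase_aqueduct(out.data, cross_area)
    elif mode == "intensity_clip":
        nz = out.data[out.data > 0]
        if nz.size:
            qv = np.quantile(nz, clip_quantile)
            out.data = np.minimum(out.data, np.float32(qv))
    out.meta["corrupted"] = mode
    return out


def _erase_aqueduct(data: np.ndarray, cross_area_mm2: float) -> np.ndarray:
    """Fill the narrow enclosed dark channel (the aqueduct) with tissue."""
    from .midsagittal import enclosed_csf_components  # local import, no cycle at runtime

    data = data.copy()
    comps = enclosed_csf_components(data)
    if comps is None:
        return data
    labels, tissue = comps
    nlab = labels.max()
    xs_mid = ndimage.center_of_mass(tissue)[0]
    best, best_z = None, np.inf
    for lab in range(1, nlab + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < 5:
            continue
        cx, _, cz = vox.mean(axis=0)
        per_z = np.bincount(vox[:, 2])
        if per_z.max() * cross_area_mm2 > 40.0:  # wide cavity: a ventricle
            continue
        if abs(cx - xs_mid) < 4 and cz < best_z:
            best, best_z = lab, cz
    if best is not None:
        grown = ndimage.binary_dilation(labels == best, iterations=2)
        data[grown] = np.median(data[data > 0.5 * data.max()])
    return data


# ---------------------------------------------------------------------------
# Scalar cohort simulation

@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    mrpi2_mean: float
    mrpi2_sd: float
    age_mean: float
    age_sd: float
    male_fraction: float = 0.5


@dataclass(frozen=True)
class CohortSimSpec:
    """Per-group Gaussian parameters for simulated MRPI 2.0 cohorts."""

    groups: tuple
    seed: int = 0

    def validate(self):
        for g in self.groups:
            if g.n < 2:
                raise ConstructionError(f"group {g.name}: n must be >= 2")
            if g.mrpi2_sd < 0 or g.age_sd < 0:
                raise ConstructionError(f"group {g.name}: SDs must be non-negative")


# Reported automated cohort parameters (mean +/- SD of MRPI 2.0 and age),
# training and testing cohorts respectively.
TRAINING_COHORT = CohortSimSpec(groups=(
    GroupSpec("PSP-P", 43, 3.25, 1.32, 71.7, 5.5, 29 / 43),
    GroupSpec("PD", 177, 1.48, 0.83, 65.8, 8.4, 104 / 177),
    GroupSpec("control", 92, 1.20, 0.53, 63.2, 8.5, 45 / 92),
))
TESTING_COHORT = CohortSimSpec(groups=(
    GroupSpec("PSP-P", 56, 4.26, 2.16, 70.6, 6.1, 37 / 56),
    GroupSpec("PD", 166, 1.65, 0.76, 64.7, 9.5, 100 / 166),
    GroupSpec("control", 91, 1.47, 0.72, 63.7, 8.9, 47 / 91),
))


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a subject table (id, group, age, sex, mrpi2) from group Gaussians.

    MRPI 2.0 values are truncated at zero by redrawing (the index is a ratio
    of positive quantities); ages are floored at 40 years to mirror the
    cohorts' inclusion criteria.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    counter = 0
    for g in spec.groups:
        vals = rng.normal(g.mrpi2_mean, g.mrpi2_sd, g.n)
        while np.any(vals <= 0):
            bad = vals <= 0
            vals[bad] = rng.normal(g.mrpi2_mean, g.mrpi2_sd, bad.sum())
        ages = np.maximum(rng.normal(g.age_mean, g.age_sd, g.n), 40.0)
        sexes = np.where(rng.random(g.n) < g.male_fraction, "M", "F")
        for v, a, sx in zip(vals, ages, sexes):
            counter += 1
            rows.append((f"sub-{counter:04d}", g.name, float(a), sx, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex", "mrpi2"])


def cohort_spec(groups_dict: dict, seed: int = 0) -> CohortSimSpec:
    """Build a CohortSimSpec from ``{name: (mean, sd, n[, age_mean, age_sd])}``."""
    gs = []
    for name, params in groups_dict.items():
        mean, sd, nn = params[0], params[1], params[2]
        age_m = params[3] if len(params) > 3 else 65.0
        age_s = params[4] if len(params) > 4 else 8.0
        gs.append(GroupSpec(name, int(nn), float(mean), float(sd), age_m, age_s))
    return CohortSimSpec(groups=tuple(gs), seed=seed)


def sweep_specs(n: int = 27, voxel_mm: float = 1.0, noise_sd: float = 0.0):
    """Deterministic phantom parameter sweep over cohort-scale magnitudes.

    Crosses three levels each of third-ventricle width, frontal-horn span
    and pons/midbrain area ratio (27 combinations); ``n`` takes the first
    ``n`` in a fixed interleaved order so small subsets still span levels.
    """
    v3s = (4.3, 5.2, 8.6)
    fhs = (30.0, 36.0, 42.0)
    areas = ((90.0, 430.0), (105.0, 520.0), (120.0, 610.0))
    combos = [(v3s[i % 3], fhs[(i // 3) % 3], areas[(i // 9) % 3])
              for i in range(27)]
    specs = []
    for i, (v3, fh, (mb, pa)) in enumerate(combos[:n]):
        specs.append(PhantomSpec(midbrain_area_mm2=mb, pons_area_mm2=pa,
                                 v3_width_mm=v3, fh_width_mm=fh,
                                 voxel_mm=voxel_mm, noise_sd=noise_sd, seed=i))
    return specs
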