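"""Synthetic micro-CT cohort generator.

Emulates the imaging substrate of a rodent micro-CT lesion/implant study:
per-subject 3D grayscale volumes containing an ellipsoidal brain, a thin
bright curved hippocampal cell layer (two mirrored sheets that widen along
the anterior-posterior axis until their dorsal and ventral components fuse),
an optional inner dentate sheet and skull shell, additive Gaussian noise and
a small rigid pose jitter.  Lesioned subjects get an excitotoxic-style
cavity that removes the cell layer plus a margin over a configurable
anterior-posterior interval anchored to the printed stereotaxic infusion
table.  Implanted subjects get bright electrode rods on a cannula grid.
LFP sessions with a shared theta oscillation, known pairwise phase offsets
and an alternating run/still speed trace are generated for the phase-offset
chain.

All outputs are pure functions of (config, seed): every random draw routes
through ``numpy.random.SeedSequence`` so cohorts regenerate identically.

Axis convention throughout: arrays are indexed (AP, DV, ML); AP index 0 is
anterior, DV index 0 is dorsal, ML index 0 is left.  World coordinates are
``index * voxel_pitch`` at voxel centers.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "INFUSION_SITES_MM",
    "bilateral_infusion_sites",
    "CohortConfig",
    "BrainVolume",
    "GroundTruth",
    "Subject",
    "Cohort",
    "CannulaSlot",
    "CannulaLayout",
    "default_cannula_layout",
    "LFPRecord",
    "SpeedTrace",
    "PhaseOffsetSpec",
    "generate_brain_volume",
    "apply_lesion",
    "insert_electrodes",
    "generate_cohort",
    "generate_lfp_session",
    "ground_truth_layer_curve",
    "save_volume",
    "load_volume",
]

# ---------------------------------------------------------------------------
# Stereotaxic infusion sites (mm from bregma; DV from dura).  The ML column
# is printed as a +/- magnitude: infusions were bilateral, so each row maps
# to two sites mirrored across the midline.
# ---------------------------------------------------------------------------

INFUSION_SITES_MM: tuple[tuple[float, float, float], ...] = (
    (-2.8, 1.4, -3.0),
    (-3.3, 2.4, -3.0),
    (-4.1, 1.8, -2.8),
    (-4.1, 3.4, -2.8),
    (-4.8, 2.0, -2.8),
    (-4.8, 4.2, -3.1),
    (-5.5, 2.6, -3.0),
    (-5.5, 3.6, -2.9),
    (-5.5, 5.0, -3.5),
    (-5.5, 5.0, -5.5),
    (-6.2, 4.0, -3.4),
    (-6.2, 5.4, -4.4),
)


def bilateral_infusion_sites() -> np.ndarray:
    """All infusion sites mirrored across the midline, shape (24, 3).

    Columns are (AP, ML, DV) in mm; each printed row yields a left (-ML)
    and a right (+ML) site.
    """
    rows = []
    for ap, ml, dv in INFUSION_SITES_MM:
        rows.append((ap, +abs(ml), dv))
        rows.append((ap, -abs(ml), dv))
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one synthetic cohort.

    Intensities are arbitrary grayscale units with the ordering
    ``electrode > layer > skull? > tissue > cavity >= 0`` enforced for the
    parts the downstream analyses rely on (layer > tissue > cavity).
    ``pose_jitter_deg`` / ``pose_jitter_vox`` bound the per-subject rigid
    perturbation (max |rotation| per axis in degrees, max |translation| per
    axis in voxels).  ``lesion_ap_extent`` is the lesioned interval as a
    fraction of the hippocampal layer's AP span.
    """

    n_control: int = 12
    n_lesion: int = 13
    grid_shape: tuple[int, int, int] = (128, 96, 96)
    voxel_pitch: float = 1.0
    tissue_intensity: float = 0.5
    layer_intensity: float = 1.0
    cavity_intensity: float = 0.1
    skull_intensity: float = 0.65
    electrode_intensity: float = 4.0
    noise_sd: float = 0.05
    pose_jitter_deg: float = 2.0
    pose_jitter_vox: float = 2.0
    lesion_ap_extent: tuple[float, float] = (0.25, 0.65)
    lesion_margin: int = 3
    include_skull: bool = True
    include_dentate: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_lesion < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not (self.layer_intensity > self.tissue_intensity > self.cavity_intensity >= 0):
            raise ValueError("need layer_intensity > tissue_intensity > cavity_intensity >= 0")
        if self.electrode_intensity <= self.layer_intensity:
            raise ValueError("electrode_intensity must exceed layer_intensity")
        lo, hi = self.lesion_ap_extent
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("lesion_ap_extent must lie within [0, 1]")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        if min(self.grid_shape) < 8:
            raise ValueError("grid too small")


@dataclass
class BrainVolume:
    """3D grayscale grid, axis order (AP, DV, ML)."""

    voxels: np.ndarray
    voxel_pitch: float = 1.0
    subject_id: str = ""
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class GroundTruth:
    """Generation-time truth attached to a synthetic subject."""

    subject_id: str
    label: str  # "control" | "lesion"
    true_rotation: np.ndarray
    true_translation: np.ndarray
    landmark_points: dict[str, np.ndarray]
    layer_mask: np.ndarray
    dentate_mask: np.ndarray | None = None
    lesioned_voxel_mask: np.ndarray | None = None
    electrode_tips: list[tuple[str, np.ndarray]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lesioned = self.lesioned_voxel_mask is not None and bool(self.lesioned_voxel_mask.any())
        if (self.label == "lesion") != lesioned:
            raise ValueError("lesioned_voxel_mask must be nonempty iff label == 'lesion'")


@dataclass
class Subject:
    volume: BrainVolume
    truth: GroundTruth


@dataclass
class Cohort:
    subjects: list[Subject]
    config: CohortConfig

    @property
    def volumes(self) -> list[BrainVolume]:
        return [s.volume for s in self.subjects]

    @property
    def truths(self) -> list[GroundTruth]:
        return [s.truth for s in self.subjects]

    @property
    def ids(self) -> list[str]:
        return [s.truth.subject_id for s in self.subjects]

    @property
    def labels(self) -> list[str]:
        return [s.truth.label for s in self.subjects]


# ---------------------------------------------------------------------------
# Parametric anatomy
#
# Per hemisphere the cell layer is a thin elliptic-arc sheet swept along AP.
# With t the fractional position along the layer's AP span, the coronal arc
# is parametrized by theta (0 at the dorsal apex, increasing laterally then
# ventrally); the dorsal and ventral components are separated by a gap
# around theta = pi/2 that shrinks linearly and closes at t = _T_FUSE, which
# defines the fusion point; its lateral extreme is the (1,1) frame landmark.
# All lengths scale with the grid so smaller test grids keep the topology.
# ---------------------------------------------------------------------------

_AP_TIP_FRAC = 0.31
_AP_END_FRAC = 0.82
_ML_CENTER_OFFSET_FRAC = 0.125  # arc center offset from midline, frac of n_ml
_R_ML_FRAC = (0.083, 0.104)     # r_ml(t)/n_ml = a + b*t
_R_DV_FRAC = (0.104, 0.083)
_DV_CENTER_FRAC = 0.42
_THETA_LO = 0.15
_GAP0 = 0.7
_T_FUSE = 0.54
_T_VENTRAL = 0.2
_HALF_THICKNESS = 0.9           # voxels
_DENTATE_RHO = 0.55
_BRAIN_SEMIAXES_FRAC = (0.44, 0.42, 0.42)
_SKULL_RATIO = 1.08


class _Geometry:
    """Grid-resolved anatomy parameters (all in voxel units)."""

    def __init__(self, grid_shape: tuple[int, int, int]):
        n_ap, n_dv, n_ml = grid_shape
        self.shape = grid_shape
        self.center = np.array([(n_ap - 1) / 2.0, (n_dv - 1) / 2.0, (n_ml - 1) / 2.0])
        self.semiaxes = np.array(
            [_BRAIN_SEMIAXES_FRAC[0] * n_ap, _BRAIN_SEMIAXES_FRAC[1] * n_dv,
             _BRAIN_SEMIAXES_FRAC[2] * n_ml]
        )
        self.ap_tip = _AP_TIP_FRAC * n_ap
        self.ap_end = _AP_END_FRAC * n_ap
        self.ml_mid = self.center[2]
        self.ml_center_offset = _ML_CENTER_OFFSET_FRAC * n_ml
        self.dv_center = _DV_CENTER_FRAC * n_dv
        self.r_ml = (_R_ML_FRAC[0] * n_ml, _R_ML_FRAC[1] * n_ml)
        self.r_dv = (_R_DV_FRAC[0] * n_dv, _R_DV_FRAC[1] * n_dv)
        # below this, the voxel-thin ventral arc fragments and the fusion
        # geometry is no longer well defined
        if self.ap_end - self.ap_tip < 20 or min(self.r_ml[0], self.r_dv[0]) < 4.9:
            raise ValueError("grid too small to contain the layer template")

    def layer_mask(self, ap, dv, ml, side: int, dentate: bool = False) -> np.ndarray:
        """Boolean membership of points in one hemisphere's sheet.

        ``side`` is +1 (right, ML > midline) or -1 (left).  ``dentate``
        selects the inner sheet at radius scale ``_DENTATE_RHO``.
        """
        t = (ap - self.ap_tip) / (self.ap_end - self.ap_tip)
        valid = (t >= 0.0) & (t <= 1.0)
        tc = np.clip(t, 0.0, 1.0)
        r_ml = self.r_ml[0] + self.r_ml[1] * tc
        r_dv = self.r_dv[0] + self.r_dv[1] * tc
        ml_c = self.ml_mid + side * self.ml_center_offset
        x = side * (ml - ml_c) / r_ml
        y = (self.dv_center - dv) / r_dv
        rho = np.hypot(x, y)
        theta = np.arctan2(x, y)
        r_eff = 0.5 * (r_ml + r_dv)
        target = _DENTATE_RHO if dentate else 1.0
        ring = np.abs(rho - target) <= _HALF_THICKNESS / r_eff
        gap = _GAP0 * np.clip(1.0 - tc / _T_FUSE, 0.0, None)
        half_pi = np.pi / 2.0
        if dentate:
            lo, hi = 0.2, np.minimum(1.9, 0.5 + 2.2 * tc)
            arcs = (theta >= lo) & (theta <= hi) & (tc >= 0.12)
        else:
            dorsal_hi = np.minimum(0.7 + 2.0 * tc, half_pi - gap / 2.0)
            dorsal = (theta >= _THETA_LO) & (theta <= dorsal_hi)
            v_lo = half_pi + gap / 2.0
            v_hi = np.minimum(2.7, half_pi + 0.3 + 2.2 * (tc - _T_VENTRAL))
            ventral = (tc >= _T_VENTRAL) & (theta >= v_lo) & (theta <= v_hi)
            arcs = dorsal | ventral
        return valid & ring & arcs

    def layer_box_canonical(self, pad: float = 3.0) -> np.ndarray:
        """Canonical-frame bounding box (2x3 min/max) of both sheets."""
        r_ml_max = self.r_ml[0] + self.r_ml[1]
        r_dv_max = self.r_dv[0] + self.r_dv[1]
        lo = [self.ap_tip - pad, self.dv_center - r_dv_max - pad,
              self.ml_mid - self.ml_center_offset - r_ml_max - pad]
        hi = [self.ap_end + pad, self.dv_center + r_dv_max + pad,
              self.ml_mid + self.ml_center_offset + r_ml_max + pad]
        return np.array([lo, hi])


def _small_rotation(angles_deg: np.ndarray) -> np.ndarray:
    """Proper rotation from per-axis angles (degrees), composed AP->DV->ML."""
    a, b, c = np.deg2rad(angles_deg)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    r_ap = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    r_dv = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    r_ml = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return r_ml @ r_dv @ r_ap


_INDEX_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _index_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Cached (3, N) float64 voxel-index array for a grid shape."""
    if shape not in _INDEX_CACHE:
        _INDEX_CACHE[shape] = np.indices(shape, dtype=np.float64).reshape(3, -1)
    return _INDEX_CACHE[shape]


def _canonical_coords(shape, rotation: np.ndarray, translation: np.ndarray, center: np.ndarray):
    """Canonical-frame coordinates of every output voxel under the pose.

    The pose maps canonical points c to output points x = R (c - ctr) + ctr
    + t; we evaluate fields at c = R^T (x - ctr - t) + ctr.
    Returns three arrays (ap, dv, ml) of the output grid's shape.
    """
    flat = _index_grid(tuple(shape))
    rel = flat - (center + translation)[:, None]
    can = rotation.T @ rel + center[:, None]
    return can.reshape((3, *shape))


# ---------------------------------------------------------------------------
# Volume generation
# ---------------------------------------------------------------------------


def generate_brain_volume(
    config: CohortConfig, subject_seed: int, subject_id: str = ""
) -> tuple[BrainVolume, GroundTruth]:
    """Generate one synthetic control brain with known ground truth.

    The volume contains (in the subject's jittered pose) an ellipsoidal
    tissue region, the bilateral curved cell-layer sheets at
    ``layer_intensity``, optionally an inner dentate sheet and a skull
    shell, plus i.i.d. Gaussian noise.  Landmarks (anterior layer tip and
    dorsal/ventral fusion point, per side) are derived from the rasterized
    layer mask so that detection can be validated voxel-for-voxel.
    """
    geom = _Geometry(config.grid_shape)
    rng = np.random.default_rng(np.random.SeedSequence(subject_seed))

    angles = rng.uniform(-config.pose_jitter_deg, config.pose_jitter_deg, size=3)
    trans = rng.uniform(-config.pose_jitter_vox, config.pose_jitter_vox, size=3)
    if config.pose_jitter_deg == 0:
        angles[:] = 0.0
    if config.pose_jitter_vox == 0:
        trans[:] = 0.0
    rot = _small_rotation(angles)

    ap, dv, ml = _canonical_coords(config.grid_shape, rot, trans, geom.center)

    ellip = (
        ((ap - geom.center[0]) / geom.semiaxes[0]) ** 2
        + ((dv - geom.center[1]) / geom.semiaxes[1]) ** 2
        + ((ml - geom.center[2]) / geom.semiaxes[2]) ** 2
    )
    vox = np.zeros(config.grid_shape, dtype=np.float64)
    vox[ellip <= 1.0] = config.tissue_intensity
    if config.include_skull:
        vox[(ellip > 1.0) & (ellip <= _SKULL_RATIO**2)] = config.skull_intensity

    # the sheets live in a small sub-box; find it in the output frame
    box = geom.layer_box_canonical()
    corners = np.array(
        [[box[i][0], box[j][1], box[k][2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    out_corners = (corners - geom.center) @ rot.T + geom.center + trans
    lo = np.maximum(np.floor(out_corners.min(axis=0)) - 1, 0).astype(int)
    hi = np.minimum(np.ceil(out_corners.max(axis=0)) + 2, config.grid_shape).astype(int)
    sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    ap_s, dv_s, ml_s = ap[sub], dv[sub], ml[sub]

    layer = np.zeros(config.grid_shape, dtype=bool)
    dentate = np.zeros(config.grid_shape, dtype=bool)
    for side in (-1, +1):
        layer[sub] |= geom.layer_mask(ap_s, dv_s, ml_s, side)
        if config.include_dentate:
            dentate[sub] |= geom.layer_mask(ap_s, dv_s, ml_s, side, dentate=True)
    vox[dentate] = config.layer_intensity
    vox[layer] = config.layer_intensity

    if config.noise_sd > 0:
        vox += rng.normal(0.0, config.noise_sd, size=config.grid_shape)

    from .alignment import landmarks_from_layer_mask  # shared landmark rule

    landmarks = landmarks_from_layer_mask(layer, ml_mid=geom.ml_mid)
    truth = GroundTruth(
        subject_id=subject_id,
        label="control",
        true_rotation=rot,
        true_translation=trans,
        landmark_points=landmarks,
        layer_mask=layer,
        dentate_mask=dentate if config.include_dentate else None,
    )
    volume = BrainVolume(
        voxels=vox.astype(np.float32),
        voxel_pitch=config.voxel_pitch,
        subject_id=subject_id,
        provenance="synthetic",
    )
    return volume, truth


def _infusion_sites_vox(config: CohortConfig, ap_lo: float, ap_hi: float,
                        geom: _Geometry) -> np.ndarray:
    """Map the 24 bilateral infusion sites into voxel coordinates.

    The printed AP range is mapped affinely onto the configured lesioned
    interval of the layer span; |ML| onto [arc center, lateral extreme];
    DV onto the dorsal arc band.  This anchors the cavity geometry to the
    stereotaxic table rather than to an arbitrary shape.
    """
    sites = bilateral_infusion_sites()
    ap_mm, ml_mm, dv_mm = sites[:, 0], sites[:, 1], sites[:, 2]
    ap01 = (ap_mm - ap_mm.max()) / (ap_mm.min() - ap_mm.max())  # 0 anterior
    ap_vox = ap_lo + ap01 * (ap_hi - ap_lo)
    t = (ap_vox - geom.ap_tip) / (geom.ap_end - geom.ap_tip)
    r_ml = geom.r_ml[0] + geom.r_ml[1] * np.clip(t, 0, 1)
    r_dv = geom.r_dv[0] + geom.r_dv[1] * np.clip(t, 0, 1)
    ml01 = (np.abs(ml_mm) - 1.0) / (6.0 - 1.0)  # printed |ML| spans ~1.4..5.4
    ml_vox = geom.ml_mid + np.sign(ml_mm) * (geom.ml_center_offset + ml01 * r_ml)
    dv01 = (np.abs(dv_mm) - 2.5) / (6.0 - 2.5)  # printed |DV| spans ~2.8..5.5
    dv_vox = geom.dv_center - r_dv * (1.0 - 1.6 * dv01)
    return np.column_stack([ap_vox, dv_vox, ml_vox])


def apply_lesion(
    volume: BrainVolume,
    truth: GroundTruth,
    config: CohortConfig,
    rng_seed: int,
) -> tuple[BrainVolume, GroundTruth]:
    """Carve a cavity over the lesioned AP interval of the cell layer.

    Voxels of the layer plus a dilated margin -- restricted to the AP
    interval ``config.lesion_ap_extent`` of the layer's span and seeded by
    spherical foci at the 24 bilateral infusion sites -- are set toward
    ``cavity_intensity`` with a randomized ragged boundary.  An empty
    interval returns the input unchanged with a warning flag.
    """
    lo, hi = config.lesion_ap_extent
    if hi <= lo:
        new_truth = dataclasses.replace(truth, warnings=truth.warnings + ["empty lesion_ap_extent"])
        return volume, new_truth

    geom = _Geometry(volume.shape)
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed))

    ap_any = np.flatnonzero(truth.layer_mask.any(axis=(1, 2)))
    a0, a1 = float(ap_any[0]), float(ap_any[-1])
    ap_lo = a0 + lo * (a1 - a0)
    ap_hi = a0 + hi * (a1 - a0)

    region = ndimage.binary_dilation(truth.layer_mask, iterations=config.lesion_margin)

    # spherical foci at the mapped infusion sites (local windows)
    sites = _infusion_sites_vox(config, ap_lo, ap_hi, geom)
    r_focus = config.lesion_margin + 1.5
    rr = int(np.ceil(r_focus))
    for site in sites:
        lo_i = np.maximum(np.floor(site - rr), 0).astype(int)
        hi_i = np.minimum(np.ceil(site + rr) + 1, volume.shape).astype(int)
        win = tuple(slice(a, b) for a, b in zip(lo_i, hi_i))
        gg = np.mgrid[win].astype(np.float64)
        d2 = ((gg[0] - site[0]) ** 2 + (gg[1] - site[1]) ** 2 + (gg[2] - site[2]) ** 2)
        region[win] |= d2 <= r_focus**2

    # ragged boundary: erode a core, keep shell voxels on a smooth noise field
    core = ndimage.binary_erosion(region, iterations=2)
    shell = region & ~core
    ragged = ndimage.gaussian_filter(rng.normal(size=volume.shape), 2.0) > 0.0
    lesion = core | (shell & ragged)

    # restrict strictly to the AP window (after dilation, so differences
    # stay inside the recorded mask and the declared interval)
    window = np.zeros(volume.shape, dtype=bool)
    window[int(np.ceil(ap_lo)) : int(np.floor(ap_hi)) + 1] = True
    lesion &= window

    vox = volume.voxels.astype(np.float64).copy()
    n = int(lesion.sum())
    vox[lesion] = config.cavity_intensity + (
        rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    )

    new_volume = BrainVolume(
        voxels=vox.astype(np.float32),
        voxel_pitch=volume.voxel_pitch,
        subject_id=volume.subject_id,
        provenance=volume.provenance,
    )
    new_truth = dataclasses.replace(truth, label="lesion", lesioned_voxel_mask=lesion)
    return new_volume, new_truth


# ---------------------------------------------------------------------------
# Electrodes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CannulaSlot:
    label: str
    ap: float  # voxel coordinates of the slot axis
    ml: float
    occupied: bool = True


@dataclass
class CannulaLayout:
    """Cannula grid of (AP, ML) slots; unoccupied slots are skipped."""

    slots: list[CannulaSlot]

    @property
    def occupied(self) -> list[CannulaSlot]:
        return [s for s in self.slots if s.occupied]

    def positions(self, occupied_only: bool = True) -> np.ndarray:
        slots = self.occupied if occupied_only else self.slots
        return np.array([[s.ap, s.ml] for s in slots], dtype=float)


def default_cannula_layout(
    config: CohortConfig, n_rows: int = 4, n_cols: int = 6,
    empty: tuple[int, ...] = (7, 13),
) -> CannulaLayout:
    """Rectangular cannula grid over the right dorsal hippocampus.

    ``empty`` marks slot indices without a tetrode (the layout's "X"s);
    the default 4 x 6 grid with 2 empty slots carries 22 tetrodes.  The
    empty pair is chosen asymmetric under a 180-degree flip so the
    occupied pattern determines the grid's orientation.
    """
    n_ap, _, n_ml = config.grid_shape
    ap0, ap1 = 0.36 * n_ap, 0.52 * n_ap
    ml0, ml1 = 0.60 * n_ml, 0.80 * n_ml
    slots = []
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            ap = ap0 + (ap1 - ap0) * (i / max(n_rows - 1, 1))
            ml = ml0 + (ml1 - ml0) * (j / max(n_cols - 1, 1))
            slots.append(CannulaSlot(label=f"tt{k:02d}", ap=ap, ml=ml, occupied=k not in empty))
            k += 1
    return CannulaLayout(slots=slots)


def insert_electrodes(
    volume: BrainVolume,
    truth: GroundTruth,
    layout: CannulaLayout,
    tip_depths: dict[str, float] | float,
    electrode_intensity: float = 4.0,
    rod_radius: float = 1.6,
) -> tuple[BrainVolume, GroundTruth]:
    """Paint bright electrode rods from the dorsal surface to each tip.

    Rods get a bright core with a radially graded edge (still far above the
    cell-layer intensity) so thresholding always keeps a connected core.
    Tips below the grid are clipped with a warning.  ``tip_depths`` is a DV
    voxel index, either one value for all slots or per-slot by label.
    """
    n_ap, n_dv, n_ml = volume.shape
    vox = volume.voxels.astype(np.float64).copy()
    tips: list[tuple[str, np.ndarray]] = []
    warns = list(truth.warnings)

    for slot in layout.occupied:
        if not (0 <= slot.ap < n_ap and 0 <= slot.ml < n_ml):
            raise ValueError(f"slot {slot.label} outside grid bounds")
        depth = tip_depths[slot.label] if isinstance(tip_depths, dict) else float(tip_depths)
        if depth > n_dv - 1:
            warns.append(f"tip of {slot.label} clipped to grid")
            depth = float(n_dv - 1)
        ai, mi = int(round(slot.ap)), int(round(slot.ml))
        r = int(np.ceil(rod_radius))
        dv_top = 2  # just above the skull shell
        dv_idx = np.arange(dv_top, int(round(depth)) + 1)
        for da in range(-r, r + 1):
            for dm in range(-r, r + 1):
                rho2 = (da * da + dm * dm) / (rod_radius * rod_radius)
                if rho2 > 1.0:
                    continue
                a, m = ai + da, mi + dm
                if 0 <= a < n_ap and 0 <= m < n_ml:
                    val = electrode_intensity * (1.0 - 0.5 * rho2)
                    vox[a, dv_idx, m] = np.maximum(vox[a, dv_idx, m], val)
        tips.append((slot.label, np.array([slot.ap, depth, slot.ml])))

    new_volume = BrainVolume(
        voxels=vox.astype(np.float32),
        voxel_pitch=volume.voxel_pitch,
        subject_id=volume.subject_id,
        provenance=volume.provenance,
    )
    new_truth = dataclasses.replace(
        truth, electrode_tips=truth.electrode_tips + tips, warnings=warns
    )
    return new_volume, new_truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def subject_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Stable per-subject seed: SeedSequence(master_seed, spawn_key=(index,))."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``n_control`` control + ``n_lesion`` lesioned subjects.

    Per-subject seeds derive deterministically from ``config.master_seed``
    (see :func:`subject_seed`); controls come first.
    """
    subjects: list[Subject] = []
    n_total = config.n_control + config.n_lesion
    for i in range(n_total):
        ss = subject_seed(config.master_seed, i)
        gen_seed, lesion_seed = (int(x) for x in ss.generate_state(2))
        is_lesion = i >= config.n_control
        sid = f"L{i - config.n_control:02d}" if is_lesion else f"C{i:02d}"
        vol, truth = generate_brain_volume(config, gen_seed, subject_id=sid)
        if is_lesion:
            vol, truth = apply_lesion(vol, truth, config, lesion_seed)
        subjects.append(Subject(volume=vol, truth=truth))
    return Cohort(subjects=subjects, config=config)


def ground_truth_layer_curve(
    truth: GroundTruth, side: int, which: str = "lateral"
) -> np.ndarray:
    """Per-AP-slice curve point from the rasterized ground-truth masks.

    ``which='lateral'`` takes the lateral-most layer voxel per slice;
    ``which='medial'`` the medial-most dentate voxel.  Returns (AP, ML)
    rows, anterior to posterior; sides split at the volume midline.
    """
    mask = truth.layer_mask if which == "lateral" else truth.dentate_mask
    if mask is None:
        return np.empty((0, 2))
    n_ml = mask.shape[2]
    mid = (n_ml - 1) / 2.0
    rows = []
    for z in range(mask.shape[0]):
        dvs, mls = np.nonzero(mask[z])
        if side > 0:
            mls = mls[mls > mid]
        else:
            mls = mls[mls < mid]
        if mls.size == 0:
            continue
        offset = side * (mls - mid)
        j = np.argmax(offset) if which == "lateral" else np.argmin(offset)
        rows.append((float(z), float(mls[j])))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# LFP sessions
# ---------------------------------------------------------------------------


@dataclass
class LFPRecord:
    """channels x samples voltage traces at ``sampling_rate`` Hz."""

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SpeedTrace:
    """Body speed (cm/s), time-aligned to the LFP start."""

    speed: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")


@dataclass
class PhaseOffsetSpec:
    """True pairwise theta structure of a synthetic session.

    ``offsets`` are per-channel phase offsets in radians relative to channel
    0 (so ``offsets[0] == 0``); channel k carries
    ``sin(2 pi f t + offsets[k])``.  ``snr`` is the RMS signal-to-noise
    ratio (``np.inf`` disables noise).
    """

    offsets: np.ndarray = field(default_factory=lambda: np.array([0.0, np.pi / 6]))
    theta_freq: float = 8.0
    snr: float = 10.0
    duration: float = 600.0

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float).copy()
        out = np.mod(off + np.pi, 2 * np.pi) - np.pi
        out[out == -np.pi] = np.pi
        if not np.allclose(out, off):
            warnings.warn("phase offsets normalized into (-pi, pi]", stacklevel=2)
        self.offsets = out
        if not (4.0 <= self.theta_freq <= 10.0):
            warnings.warn("theta frequency outside the default [4, 10] Hz pass band",
                          stacklevel=2)


def generate_lfp_session(
    spec: PhaseOffsetSpec,
    fs: float = 1500.0,
    speed_pattern: list[tuple[float, float]] | None = None,
    speed_fs: float = 25.0,
    seed: int = 0,
) -> tuple[LFPRecord, SpeedTrace]:
    """Synthesize a multichannel theta session plus aligned speed trace.

    Channel k is ``sin(2 pi f t + offsets[k])`` plus white noise scaled so
    the RMS signal/noise ratio equals ``spec.snr``.  ``speed_pattern`` is a
    list of (duration_s, speed_cm_s) epochs cycled until the session ends;
    the default alternates 20 s running at 25 cm/s with 10 s still at
    3 cm/s.
    """
    if fs < 4 * spec.theta_freq:
        raise ValueError("sampling rate must be at least 4x the theta frequency")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    data = np.sin(
        2 * np.pi * spec.theta_freq * t[None, :] + np.asarray(spec.offsets)[:, None]
    )
    if np.isfinite(spec.snr):
        noise_sd = (1.0 / np.sqrt(2.0)) / spec.snr
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    if speed_pattern is None:
        speed_pattern = [(20.0, 25.0), (10.0, 3.0)]
    n_speed = int(round(spec.duration * speed_fs))
    speed = np.empty(n_speed)
    pos = 0
    k = 0
    while pos < n_speed:
        dur, val = speed_pattern[k % len(speed_pattern)]
        m = int(round(dur * speed_fs))
        speed[pos : pos + m] = val
        pos += m
        k += 1
    return LFPRecord(data=data, sampling_rate=fs), SpeedTrace(speed=speed, sampling_rate=speed_fs)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def save_volume(volume: BrainVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or multi-page TIFF (.tif).

    TIFF pages are AP slices; NIfTI stores the (AP, DV, ML) grid with the
    voxel pitch on the diagonal affine.
    """
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, volume.voxels.astype(np.float32))
    else:
        import nibabel as nib

        affine = np.diag([volume.voxel_pitch] * 3 + [1.0])
        nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def load_volume(path: str | Path, subject_id: str = "") -> BrainVolume:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        vox = tifffile.imread(path)
        pitch = 1.0
    else:
        import nibabel as nib

        img = nib.load(str(path))
        vox = np.asarray(img.dataobj, dtype=np.float32)
        pitch = float(abs(img.affine[0, 0])) or 1.0
    return BrainVolume(voxels=vox, voxel_pitch=pitch,
                       subject_id=subject_id or path.stem, provenance="file")


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth labels/landmarks/tips as JSON (masks are not included)."""
    payload = {
        "subject_id": truth.subject_id,
        "label": truth.label,
        "true_rotation": truth.true_rotation.tolist(),
        "true_translation": truth.true_translation.tolist(),
        "landmark_points": {k: v.tolist() for k, v in truth.landmark_points.items()},
        "electrode_tips": [[lab, tip.tolist()] for lab, tip in truth.electrode_tips],
        "warnings": truth.warnings,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
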