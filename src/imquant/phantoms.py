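"""Synthetic phantoms with analytic ground truth.

Every generator is deterministic given its seed and returns, next to the
image/mask objects, a plain-dict ground-truth record carrying the analytic
quantities (volumes, gaps, thicknesses, coverage fractions, informative
feature indices) that downstream tests measure against.

Default CT intensity anchors: lung parenchyma -800 HU, pneumonia lesions
-100 +/- 50 HU, soft tissue 40 HU, bone 700 HU. These are plausible
Hounsfield values chosen once for testability, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .grid import ImageVolume, LabelMask

__all__ = [
    "PhantomSpec",
    "LungLabels",
    "make_geometric_phantom",
    "make_lung_phantom",
    "make_knee_phantom",
    "make_brain_phantom",
    "make_feature_dataset",
]

HU_LUNG = -800.0
HU_LESION = -100.0
HU_LESION_SD = 50.0
HU_SOFT = 40.0
HU_BONE = 700.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + intensity model for a simple geometric phantom."""

    kind: Literal["sphere", "ellipsoid", "slab", "two_plates"] = "sphere"
    shape: tuple[int, int, int] = (48, 48, 48)          # grid, [z, y, x]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z) mm
    radius_mm: float = 10.0
    semi_axes_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)  # (x, y, z)
    slab_thickness_mm: float = 5.0
    plate_gap_mm: float = 4.0
    foreground: float = 200.0
    background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


def _voxel_centers(shape, spacing):
    """World (x, y, z) coordinate grids for array axes [z, y, x]."""
    sx, sy, sz = spacing
    nz, ny, nx = shape
    z, y, x = np.meshgrid(
        np.arange(nz) * sz, np.arange(ny) * sy, np.arange(nx) * sx, indexing="ij"
    )
    return x, y, z


def make_geometric_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelMask, dict]:
    """Rasterize an analytic shape (centre-of-voxel rule) with optional noise."""
    x, y, z = _voxel_centers(spec.shape, spec.spacing)
    cx = (spec.shape[2] - 1) * spec.spacing[0] / 2
    cy = (spec.shape[1] - 1) * spec.spacing[1] / 2
    cz = (spec.shape[0] - 1) * spec.spacing[2] / 2
    truth: dict = {"kind": spec.kind, "centroid_mm": (cx, cy, cz)}

    if spec.kind == "sphere":
        r = spec.radius_mm
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        truth["volume_mm3"] = 4.0 / 3.0 * np.pi * r**3
        truth["surface_mm2"] = 4.0 * np.pi * r**2
        truth["radius_mm"] = r
    elif spec.kind == "ellipsoid":
        a, b, c = spec.semi_axes_mm
        inside = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
        truth["volume_mm3"] = 4.0 / 3.0 * np.pi * a * b * c
        truth["semi_axes_mm"] = (a, b, c)
    elif spec.kind == "slab":
        t = spec.slab_thickness_mm
        inside = np.abs(z - cz) <= t / 2.0
        truth["thickness_mm"] = t
    elif spec.kind == "two_plates":
        g = spec.plate_gap_mm
        t = spec.slab_thickness_mm
        inside = (np.abs(z - (cz - g / 2.0 - t / 2.0)) <= t / 2.0) | (
            np.abs(z - (cz + g / 2.0 + t / 2.0)) <= t / 2.0
        )
        truth["gap_mm"] = g
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    if not inside.any():
        raise ValueError("shape does not intersect the grid — enlarge the grid")
    if inside.all():
        raise ValueError("shape exceeds the grid — enlarge the grid")

    img = np.where(inside, spec.foreground, spec.background).astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    vol = ImageVolume(img, spec.spacing)
    mask = LabelMask(inside.astype(np.int16), spec.spacing, label_names={1: spec.kind})
    truth["voxel_count"] = int(inside.sum())
    truth["voxel_volume_mm3"] = truth["voxel_count"] * float(np.prod(spec.spacing))
    return vol, mask, truth


# ---------------------------------------------------------------------------
# Lung phantom: 2 lungs -> 5 lobes -> 18 bronchopulmonary segments + lesions
# ---------------------------------------------------------------------------

# lobe -> number of segments, mirroring the clinical 18-segment scheme
# (right upper 3, right middle 2, right lower 5, left upper 4, left lower 4)
LOBE_SEGMENTS = {1: 3, 2: 2, 3: 5, 4: 4, 5: 4}
LOBE_NAMES = {
    1: "right_upper_lobe", 2: "right_middle_lobe", 3: "right_lower_lobe",
    4: "left_upper_lobe", 5: "left_lower_lobe",
}
RIGHT_LOBES = (1, 2, 3)
LEFT_LOBES = (4, 5)


@dataclass
class LungLabels:
    """Hierarchical lung labels on one grid: lobes (1..5) and segments (1..18).

    Segments nest exactly inside lobes; ``segment_lobe`` maps each segment
    label to its parent lobe.
    """

    lobes: LabelMask
    segments: LabelMask
    segment_lobe: dict[int, int] = field(default_factory=dict)

    @property
    def lung_sides(self) -> dict[str, np.ndarray]:
        lob = self.lobes.data
        return {
            "right": np.isin(lob, RIGHT_LOBES),
            "left": np.isin(lob, LEFT_LOBES),
        }


def make_lung_phantom(
    shape: tuple[int, int, int] = (80, 56, 88),
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5),
    lesion_volumes_cm3: tuple[float, ...] = (50.0,),
    lesion_lobes: tuple[int, ...] = (3,),
    noise_sd: float = 20.0,
    seed: int = 0,
) -> tuple[ImageVolume, LungLabels, LabelMask, dict]:
    """Two ellipsoidal lungs partitioned into 5 lobes and 18 nested segments.

    Lesions are spheres of the requested volumes placed at the centroid of
    their host lobes, with HU ~ N(-100, 50). Raises if a lesion cannot fit
    inside its lobe.
    """
    rng = np.random.default_rng(seed)
    x, y, z = _voxel_centers(shape, spacing)
    ext_x = (shape[2] - 1) * spacing[0]
    ext_y = (shape[1] - 1) * spacing[1]
    ext_z = (shape[0] - 1) * spacing[2]

    # two ellipsoids side by side along x; +x = patient left (LPS)
    a, b, c = 0.21 * ext_x, 0.40 * ext_y, 0.42 * ext_z
    cy, cz = ext_y / 2, ext_z / 2
    right_cx, left_cx = 0.27 * ext_x, 0.73 * ext_x
    right = ((x - right_cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1
    left = ((x - left_cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1

    lobes = np.zeros(shape, dtype=np.int16)
    # split by z (cranio-caudal) into slabs with roughly equal voxel counts
    for side_mask, lobe_ids in ((right, RIGHT_LOBES), (left, LEFT_LOBES)):
        zin = z[side_mask]
        qs = np.quantile(zin, np.linspace(0, 1, len(lobe_ids) + 1))
        qs[0] -= 1.0
        for i, lid in enumerate(lobe_ids):
            sel = side_mask & (z > qs[i]) & (z <= qs[i + 1])
            lobes[sel] = lid

    segments = np.zeros(shape, dtype=np.int16)
    segment_lobe: dict[int, int] = {}
    seg_id = 0
    for lid, nseg in LOBE_SEGMENTS.items():
        sel = lobes == lid
        yin = y[sel]
        qs = np.quantile(yin, np.linspace(0, 1, nseg + 1))
        qs[0] -= 1.0
        for i in range(nseg):
            seg_id += 1
            seg_sel = sel & (y > qs[i]) & (y <= qs[i + 1])
            segments[seg_sel] = seg_id
            segment_lobe[seg_id] = lid

    voxvol = float(np.prod(spacing))
    lesion = np.zeros(shape, dtype=np.int16)
    truth_lesions = []
    for li, (vol_cm3, lobe_id) in enumerate(zip(lesion_volumes_cm3, lesion_lobes), start=1):
        r = (3.0 * vol_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        sel = lobes == lobe_id
        if not sel.any():
            raise ValueError(f"lobe {lobe_id} empty")
        lcx, lcy, lcz = x[sel].mean(), y[sel].mean(), z[sel].mean()
        ball = (x - lcx) ** 2 + (y - lcy) ** 2 + (z - lcz) ** 2 <= r**2
        if (ball & ~sel).sum() > 0.02 * ball.sum():
            raise ValueError(
                f"lesion of {vol_cm3} cm3 does not fit inside lobe {lobe_id}"
            )
        ball &= lobes > 0
        lesion[ball] = li
        truth_lesions.append({
            "label": li, "lobe": lobe_id, "volume_cm3": vol_cm3,
            "rasterized_cm3": float(ball.sum() * voxvol / 1000.0),
        })

    ct = np.full(shape, HU_SOFT)
    ct[lobes > 0] = HU_LUNG
    les = lesion > 0
    ct[les] = HU_LESION + rng.normal(0.0, HU_LESION_SD, size=int(les.sum()))
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, size=shape)

    ct_vol = ImageVolume(ct, spacing)
    lobes_mask = LabelMask(lobes, spacing, label_names=dict(LOBE_NAMES))
    seg_mask = LabelMask(segments, spacing,
                         label_names={i: f"segment_{i:02d}" for i in range(1, 19)})
    lesion_mask = LabelMask(lesion, spacing, label_names={i + 1: f"lesion_{i + 1}"
                                                          for i in range(len(truth_lesions))})
    labels = LungLabels(lobes_mask, seg_mask, segment_lobe)
    truth = {
        "lobe_volumes_mm3": {int(l): float((lobes == l).sum() * voxvol) for l in range(1, 6)},
        "lung_volume_mm3": float((lobes > 0).sum() * voxvol),
        "lesions": truth_lesions,
    }
    return ct_vol, labels, lesion_mask, truth


# ---------------------------------------------------------------------------
# Knee phantom
# ---------------------------------------------------------------------------

def make_knee_phantom(
    shape: tuple[int, int, int] = (72, 56, 96),
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
    gap_mm: float = 4.0,
    cartilage_thickness_mm: float = 3.0,
    meniscus_coverage: float = 0.5,
) -> tuple[dict[str, LabelMask], dict]:
    """Plate-and-slab knee assembly with a known joint gap.

    Femur and tibia are parallel plates whose facing surfaces are ``gap_mm``
    apart; cartilages are uniform slabs of the requested thickness; the
    meniscus covers ``meniscus_coverage`` of the tibial-cartilage axial
    footprint (laterally outermost columns, as in a ring-shaped meniscus).
    Each structure is a separate mask, so slabs may share world space.
    """
    if gap_mm < 0:
        raise ValueError("gap must be non-negative")
    x, y, z = _voxel_centers(shape, spacing)
    ext_z = (shape[0] - 1) * spacing[2]
    cz = ext_z / 2
    sx, sy, sz = spacing
    t_bone = 6 * sz

    # bone surfaces (voxel-edge to voxel-edge) gap_mm apart around cz
    tib_top = cz - gap_mm / 2.0
    fem_bot = cz + gap_mm / 2.0
    in_x = (x >= 4 * sx) & (x <= (shape[2] - 5) * sx)
    in_y = (y >= 4 * sy) & (y <= (shape[1] - 5) * sy)
    footprint = in_x & in_y
    tibia = footprint & (z < tib_top) & (z >= tib_top - t_bone)
    femur = footprint & (z > fem_bot) & (z <= fem_bot + t_bone)
    patella = footprint & (z >= fem_bot + t_bone + 2 * sz) & (z <= fem_bot + t_bone + 4 * sz)

    # cartilage slabs: tibial inside the gap, femoral/patellar stacked above
    # the femur band (separate masks, so sharing z with bone is fine, but the
    # three cartilages must not overlap on their shared label array)
    tc = cartilage_thickness_mm
    tib_cart = footprint & (z >= tib_top) & (z < tib_top + tc)
    fem_cart = footprint & (z >= fem_bot) & (z < fem_bot + tc)
    pat_cart = footprint & (z >= fem_bot + t_bone + tc) & (z < fem_bot + t_bone + 2 * tc)

    # meniscus: cover a fraction of the tibial cartilage footprint in x
    xs = np.unique(x[tib_cart])
    n_cover = int(round(meniscus_coverage * xs.size))
    covered = np.isin(x, xs[:n_cover])
    meniscus = tib_cart & covered  # same z-band; separate mask

    def mk(arr, name):
        return LabelMask(arr.astype(np.int16), spacing, label_names={1: name})

    bones = np.zeros(shape, dtype=np.int16)
    bones[femur] = 1
    bones[tibia] = 2
    bones[patella] = 3
    cartilages = np.zeros(shape, dtype=np.int16)
    cartilages[fem_cart] = 1
    cartilages[tib_cart] = 2
    cartilages[pat_cart] = 3
    masks = {
        "bones": LabelMask(bones, spacing,
                           label_names={1: "femur", 2: "tibia", 3: "patella"}),
        "cartilages": LabelMask(cartilages, spacing,
                                label_names={1: "femoral_cartilage",
                                             2: "tibial_cartilage",
                                             3: "patellar_cartilage"}),
        "menisci": mk(meniscus, "meniscus"),
    }
    realized_cov = float(n_cover) / float(xs.size)
    truth = {
        "gap_mm": gap_mm,
        "cartilage_thickness_mm": cartilage_thickness_mm,
        "coverage": realized_cov,
    }
    return masks, truth


# ---------------------------------------------------------------------------
# Brain phantom: 109-region parcellation + synthetic normative table
# ---------------------------------------------------------------------------

N_BRAIN_REGIONS = 109
_N_PAIRS = 54  # 54 mirrored pairs + 1 midline region = 109


def brain_region_names() -> dict[int, str]:
    names = {}
    for p in range(_N_PAIRS):
        names[2 * p + 1] = f"region_{p + 1:02d}_left"
        names[2 * p + 2] = f"region_{p + 1:02d}_right"
    names[N_BRAIN_REGIONS] = "midline_csf"
    return names


def brain_pairing() -> dict[int, int]:
    """left-label -> right-label map for the 54 mirrored pairs."""
    return {2 * p + 1: 2 * p + 2 for p in range(_N_PAIRS)}


def make_brain_phantom(
    shape: tuple[int, int, int] = (64, 64, 72),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    subject_scale: float = 1.0,
    volume_cv: float = 0.10,
    n_normals: int = 1000,
    seed: int = 0,
    mirrored: bool = False,
) -> tuple[LabelMask, pd.DataFrame, dict]:
    """Labeled 109-region brain-like parcellation plus a normative table.

    Regions are boxes on a lattice: 54 left/right mirrored pairs plus one
    midline region. Per-region volumes follow log-normal distributions
    (coefficient of variation ``volume_cv``); the normative table is built
    from ``n_normals`` simulated normal subjects (5th/50th/95th percentile
    of volume and volume ratio per region, one all-comers sex/age band).
    With ``mirrored=True`` the subject's right boxes are exact mirror
    copies of the left (asymmetry index 0 by construction).
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    if nx < 24 or ny < 24 or nz < 24:
        raise ValueError("grid too small for the 109-region lattice")

    # lattice of cells in the left half (x < nx/2); mirror for right labels
    half = nx // 2
    ncell_x, ncell_y, ncell_z = 3, 5, 4  # 60 cells >= 54 pairs
    cell = (nz // ncell_z, ny // ncell_y, half // ncell_x)
    sigma = np.sqrt(np.log(1.0 + volume_cv**2))

    # per-region mean box edge (voxels); deterministic across subjects
    base_rng = np.random.default_rng(12345)
    base_edges = base_rng.integers(4, min(cell) - 1, size=_N_PAIRS)

    def draw_edges(r: np.random.Generator) -> np.ndarray:
        # log-normal volume scatter -> cube-root scatter on the edge
        factors = np.exp(r.normal(0.0, sigma, size=_N_PAIRS) / 3.0)
        return base_edges * factors * subject_scale ** (1.0 / 3.0)

    labels = np.zeros(shape, dtype=np.int16)
    edges_l = draw_edges(rng)
    edges_r = edges_l if mirrored else draw_edges(rng)
    pair = 0
    for iz in range(ncell_z):
        for iy in range(ncell_y):
            for ix in range(ncell_x):
                if pair >= _N_PAIRS:
                    break
                z0 = iz * cell[0] + 1
                y0 = iy * cell[1] + 1
                x0 = ix * cell[2] + 1
                for side, edges in (("left", edges_l), ("right", edges_r)):
                    e = max(2, int(round(edges[pair])))
                    e = min(e, min(cell) - 1)
                    lab = 2 * pair + 1 if side == "left" else 2 * pair + 2
                    if side == "left":
                        xs = slice(x0, x0 + e)
                    else:  # mirror across the midplane
                        xs = slice(nx - (x0 + e), nx - x0)
                    labels[z0:z0 + e, y0:y0 + e, xs] = lab
                pair += 1

    # midline region: a thin column on the symmetry plane
    labels[2:-2, 2:-2, half - 1:half + 1] = N_BRAIN_REGIONS

    mask = LabelMask(labels, spacing, label_names=brain_region_names())
    table = simulate_normative_table(base_edges, sigma, spacing,
                                     n_normals=n_normals, seed=seed + 1)
    voxvol = float(np.prod(spacing))
    vols = {int(l): float((labels == l).sum() * voxvol)
            for l in range(1, N_BRAIN_REGIONS + 1)}
    truth = {"volumes_mm3": vols, "n_pairs": _N_PAIRS}
    return mask, table, truth


def simulate_normative_table(base_edges: np.ndarray, sigma: float,
                             spacing, n_normals: int = 1000,
                             seed: int = 1) -> pd.DataFrame:
    """Normative percentile table from simulated normal subjects.

    Each subject's per-region volume is ``(edge * exp(N(0, sigma)/3))^3``
    scaled by the voxel volume — the same generative model the phantom
    rasterizes — so the table is the matched reference population.
    """
    rng = np.random.default_rng(seed)
    voxvol = float(np.prod(spacing))
    rows = []
    n_pairs = base_edges.size
    factors = np.exp(rng.normal(0.0, sigma, size=(n_normals, 2 * n_pairs)) / 3.0)
    edges = np.repeat(base_edges, 2)[None, :] * factors
    vols = edges**3 * voxvol  # continuous generative volumes (no rasterization)
    icv = vols.sum(axis=1)
    names = brain_region_names()
    for j in range(2 * n_pairs):
        lab = j + 1
        p5, p50, p95 = np.percentile(vols[:, j], [5, 50, 95])
        r5, r50, r95 = np.percentile(vols[:, j] / icv, [5, 50, 95])
        rows.append({
            "region": lab, "region_name": names[lab], "sex": "any",
            "age_lo": 0, "age_hi": 120,
            "p5": p5, "p50": p50, "p95": p95,
            "ratio_p5": r5, "ratio_p50": r50, "ratio_p95": r95,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular feature dataset with planted informative features
# ---------------------------------------------------------------------------

def make_feature_dataset(
    n: int = 300,
    p: int = 100,
    n_informative: int = 3,
    effect_size: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Balanced two-class table: ``n_informative`` features shifted by
    ``effect_size`` standard deviations between classes, the rest pure noise.
    """
    if not 0 <= n_informative <= p:
        raise ValueError("n_informative must be in [0, p]")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[n // 2:] = 1
    X = rng.normal(0.0, 1.0, size=(n, p))
    informative = rng.choice(p, size=n_informative, replace=False)
    X[np.ix_(labels == 1, informative)] += effect_size
    cols = [f"feat_{j:03d}" for j in range(p)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(n)])
    df["label"] = labels
    truth = {"informative": sorted(cols[j] for j in informative),
             "effect_size": effect_size}
    return df, truth
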