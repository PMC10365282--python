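"""Organ quantification reports: brain volumetry with normative flags, the
96-feature pneumonia severity block, and knee morphometrics.

All computations start from supplied label masks (segmentation itself is
out of scope). Surface areas come from marching-cubes triangulations in
physical coordinates; distances are Euclidean in world mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .grid import ImageVolume, LabelMask, check_aligned
from .phantoms import LEFT_LOBES, LOBE_SEGMENTS, RIGHT_LOBES, LungLabels

logger = logging.getLogger(__name__)

__all__ = [
    "region_volumes", "asymmetry_index", "normative_flags", "BrainReport",
    "brain_report", "PneumoniaReport", "pneumonia_features",
    "longitudinal_change", "KneeReport", "knee_metrics",
]

PNEUMONIA_SCHEMA_VERSION = "1.0"
INFECTED_FRACTION_THRESHOLD = 1e-3  # region counts as infected above 0.1% occupancy
HISTOGRAM_RANGE_HU = (-1024.0, 1024.0)
HISTOGRAM_BINS = 32


def _mesh_area(binary: np.ndarray, spacing_xyz) -> float:
    if not binary.any():
        return 0.0
    padded = np.pad(binary, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, spacing=np.asarray(spacing_xyz[::-1], dtype=float))
    return float(measure.mesh_surface_area(verts, faces))


# ---------------------------------------------------------------------------
# Brain
# ---------------------------------------------------------------------------

def region_volumes(mask: LabelMask,
                   reference_labels: list[int] | None = None
                   ) -> dict[int, dict[str, float]]:
    """Per-region volume (mm^3) and volume ratio.

    The ratio denominator is the summed volume of ``reference_labels``
    (default: every nonzero label — for the brain this is the intracranial
    volume including CSF).
    """
    voxvol = mask.voxel_volume
    labels = mask.labels
    counts = np.bincount(mask.data.ravel())
    if reference_labels is None:
        reference_labels = [int(l) for l in labels]
    ref_volume = sum(counts[l] for l in reference_labels if l < len(counts)) * voxvol
    if ref_volume == 0:
        raise ValueError("reference volume is zero")
    return {
        int(l): {"volume_mm3": counts[l] * voxvol,
                 "ratio": counts[l] * voxvol / ref_volume}
        for l in labels
    }


def asymmetry_index(left_volume: float, right_volume: float) -> float:
    """Normalized left-right difference ``2(L - R)/(L + R)``, in [-2, 2]."""
    if left_volume + right_volume <= 0:
        raise ValueError("both volumes are zero")
    return float(2.0 * (left_volume - right_volume) / (left_volume + right_volume))


def normative_flags(measurements: dict[int, float], table: pd.DataFrame,
                    sex: str, age: float,
                    value_columns: tuple[str, str] = ("p5", "p95")
                    ) -> dict[int, str]:
    """Percentile flags against a normative table.

    A value below the 5th percentile of the matched reference band flags
    ``atrophic``, above the 95th ``enlarged``, otherwise ``normal``.
    """
    lo_col, hi_col = value_columns
    flags: dict[int, str] = {}
    for region, value in measurements.items():
        band = table[(table["region"] == region)
                     & (table["sex"].isin([sex, "any"]))
                     & (table["age_lo"] <= age) & (age <= table["age_hi"])]
        if band.empty:
            raise ValueError(
                f"no normative band for region {region}, sex {sex!r}, age {age}")
        row = band.iloc[0]
        if value < row[lo_col]:
            flags[region] = "atrophic"
        elif value > row[hi_col]:
            flags[region] = "enlarged"
        else:
            flags[region] = "normal"
    return flags


@dataclass
class BrainReport:
    volumes: dict[int, dict[str, float]]
    asymmetry: dict[int, float]          # keyed by left label of each pair
    flags: dict[int, str]


def brain_report(mask: LabelMask, table: pd.DataFrame, sex: str, age: float,
                 pairing: dict[int, int]) -> BrainReport:
    """Volumes, ratios, pairwise asymmetry indices and normative flags."""
    vols = region_volumes(mask)
    asym = {}
    for left, right in pairing.items():
        lv = vols.get(left, {}).get("volume_mm3", 0.0)
        rv = vols.get(right, {}).get("volume_mm3", 0.0)
        if lv + rv > 0:
            asym[left] = asymmetry_index(lv, rv)
    flags = normative_flags({r: v["volume_mm3"] for r, v in vols.items()
                             if (table["region"] == r).any()},
                            table, sex, age)
    return BrainReport(vols, asym, flags)


# ---------------------------------------------------------------------------
# Pneumonia
# ---------------------------------------------------------------------------

@dataclass
class PneumoniaReport:
    """The 96-feature severity block: 26 volumetric + 31 numeric +
    32 histogram + 7 surface features, each an ordered name->value map."""

    volumetric: dict[str, float]
    numeric: dict[str, float]
    histogram: dict[str, float]
    surface: dict[str, float]
    schema_version: str = PNEUMONIA_SCHEMA_VERSION

    def __post_init__(self) -> None:
        sizes = (len(self.volumetric), len(self.numeric),
                 len(self.histogram), len(self.surface))
        if sizes != (26, 31, 32, 7):
            raise ValueError(f"block sizes {sizes} != (26, 31, 32, 7)")

    def as_vector(self) -> pd.Series:
        out: dict[str, float] = {}
        for block, prefix in ((self.volumetric, "vol"), (self.numeric, "num"),
                              (self.histogram, "hist"), (self.surface, "surf")):
            for k, v in block.items():
                out[f"{prefix}_{k}"] = v
        return pd.Series(out)


def pneumonia_features(ct: ImageVolume, lungs: LungLabels,
                       lesion_mask: LabelMask) -> PneumoniaReport:
    """Location-specific infection burden features from CT + lung labels."""
    lobes = lungs.lobes
    segments = lungs.segments
    for m in (lobes, segments, lesion_mask):
        if not check_aligned(ct, m):
            raise ValueError("CT, lung labels and lesion mask must share a grid")
    lung_bin = lobes.binary()
    if not lung_bin.any():
        raise ValueError("empty lung mask")
    lesion = lesion_mask.binary()
    outside = lesion & ~lung_bin
    if outside.any():
        logger.warning("%d lesion voxels outside the lungs ignored", int(outside.sum()))
        lesion = lesion & lung_bin

    voxvol = ct.voxel_volume
    sides = lungs.lung_sides
    regions: dict[str, np.ndarray] = {
        "whole_lung": lung_bin, "left_lung": sides["left"], "right_lung": sides["right"],
    }
    for lid in range(1, 6):
        regions[f"lobe_{lid}"] = lobes.data == lid

    # --- volumetric block (26) ---
    volumetric: dict[str, float] = {}
    for name, reg in regions.items():
        inf = float((lesion & reg).sum() * voxvol)
        vol = float(reg.sum() * voxvol)
        volumetric[f"infection_volume_{name}"] = inf
        volumetric[f"infection_percent_{name}"] = 100.0 * inf / vol if vol > 0 else 0.0
    for name, reg in regions.items():
        volumetric[f"region_volume_{name}"] = float(reg.sum() * voxvol)
    comp, n_comp = ndimage.label(lesion, structure=ndimage.generate_binary_structure(3, 3))
    total_lesion = float(lesion.sum() * voxvol)
    volumetric["total_lesion_volume"] = total_lesion
    volumetric["mean_lesion_volume"] = total_lesion / n_comp if n_comp else 0.0

    # --- numeric block (31) ---
    numeric: dict[str, float] = {}
    infected_lobes = 0
    for lid in range(1, 6):
        reg = lobes.data == lid
        frac = (lesion & reg).sum() / max(reg.sum(), 1)
        flag = float(frac > INFECTED_FRACTION_THRESHOLD)
        numeric[f"infected_lobe_{lid}"] = flag
        infected_lobes += int(flag)
    infected_segments = 0
    for sid in range(1, 19):
        reg = segments.data == sid
        frac = (lesion & reg).sum() / max(reg.sum(), 1)
        flag = float(frac > INFECTED_FRACTION_THRESHOLD)
        numeric[f"infected_segment_{sid}"] = flag
        infected_segments += int(flag)
    numeric["n_infected_lobes"] = float(infected_lobes)
    numeric["n_infected_segments"] = float(infected_segments)
    numeric["n_lesion_components"] = float(n_comp)
    for side in ("left", "right"):
        _, n_side = ndimage.label(lesion & sides[side],
                                  structure=ndimage.generate_binary_structure(3, 3))
        numeric[f"n_lesion_components_{side}"] = float(n_side)
    numeric["infected_lobe_fraction"] = infected_lobes / 5.0
    numeric["infected_segment_fraction"] = infected_segments / 18.0
    if n_comp:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n_comp + 1))
        numeric["largest_lesion_voxels"] = float(np.max(sizes))
    else:
        numeric["largest_lesion_voxels"] = 0.0

    # --- histogram block (32) ---
    edges = np.linspace(*HISTOGRAM_RANGE_HU, HISTOGRAM_BINS + 1)
    if lesion.any():
        hist, _ = np.histogram(np.clip(ct.data[lesion], *HISTOGRAM_RANGE_HU), bins=edges)
        hist = hist / hist.sum()
    else:
        hist = np.zeros(HISTOGRAM_BINS)
    histogram = {f"hu_bin_{i:02d}": float(hist[i]) for i in range(HISTOGRAM_BINS)}

    # --- surface block (7) ---
    sp = ct.spacing
    lesion_area = _mesh_area(lesion, sp)
    lung_area = _mesh_area(lung_bin, sp)
    left_area = _mesh_area(lesion & sides["left"], sp)
    right_area = _mesh_area(lesion & sides["right"], sp)
    contact = _face_contact_area(lesion, ~lung_bin, sp)
    surface = {
        "lesion_surface_area": lesion_area,
        "lung_boundary_surface_area": lung_area,
        "lesion_pleura_contact_area": contact,
        "lesion_surface_to_volume": lesion_area / total_lesion if total_lesion else 0.0,
        "lesion_surface_area_left": left_area,
        "lesion_surface_area_right": right_area,
        "pleura_contact_fraction": contact / lesion_area if lesion_area else 0.0,
    }
    return PneumoniaReport(volumetric, numeric, histogram, surface)


def _face_contact_area(a: np.ndarray, b: np.ndarray, spacing_xyz) -> float:
    """Total area of voxel faces where ``a`` touches ``b`` (6-neighbourhood)."""
    sx, sy, sz = spacing_xyz
    face_area = {0: sx * sy, 1: sx * sz, 2: sy * sz}  # perpendicular to z, y, x
    total = 0.0
    for axis in range(3):
        for d in (1, -1):
            shifted = np.roll(b, d, axis=axis)
            # roll wraps; zero the wrapped border slab
            sl = [slice(None)] * 3
            sl[axis] = 0 if d == 1 else -1
            shifted[tuple(sl)] = False
            total += float((a & shifted).sum()) * face_area[axis]
    return total


def longitudinal_change(report_t0: PneumoniaReport,
                        report_t1: PneumoniaReport) -> dict[str, float]:
    """Per-feature deltas (t1 - t0) across all four blocks."""
    if report_t0.schema_version != report_t1.schema_version:
        raise ValueError("pneumonia report schema versions differ")
    v0 = report_t0.as_vector()
    v1 = report_t1.as_vector()
    return (v1 - v0).to_dict()


# ---------------------------------------------------------------------------
# Knee
# ---------------------------------------------------------------------------

@dataclass
class KneeReport:
    volumes_mm3: dict[str, float]
    mean_thickness_mm: dict[str, float]
    mjsw_medial_mm: float
    mjsw_lateral_mm: float
    meniscus_coverage: float
    extras: dict = field(default_factory=dict)


def _surface_points_mm(binary: np.ndarray, spacing_xyz) -> np.ndarray:
    surf = binary & ~ndimage.binary_erosion(binary)
    pts = np.argwhere(surf).astype(float)
    return pts[:, ::-1] * np.asarray(spacing_xyz)  # world (x, y, z) mm


def _min_distance(a_pts: np.ndarray, b_pts: np.ndarray) -> float:
    if len(a_pts) == 0 or len(b_pts) == 0:
        return float("nan")
    tree = cKDTree(b_pts)
    d, _ = tree.query(a_pts, k=1)
    return float(d.min())


def _mean_thickness(binary: np.ndarray, spacing_xyz) -> float:
    """Mean local thickness: doubled distance-to-boundary sampled on the
    morphological skeleton (inscribed-sphere approximation)."""
    if not binary.any():
        return 0.0
    edt = ndimage.distance_transform_edt(binary, sampling=np.asarray(spacing_xyz[::-1]))
    skel = morphology.skeletonize(binary)
    if not skel.any():
        skel = edt == edt.max()
    return float(2.0 * edt[skel].mean())


def knee_metrics(bones: LabelMask, cartilages: LabelMask, menisci: LabelMask,
                 damage: LabelMask | None = None,
                 knee_side: str = "right",
                 femur_label: int = 1, tibia_label: int = 2) -> KneeReport:
    """Morphometrics for knee OA assessment.

    mJSW is the minimal Euclidean distance (world mm) between femoral and
    tibial bone-surface voxel centres, computed separately in the medial
    and lateral compartments (sagittal split through the tibial centroid;
    for a right knee the medial compartment lies at larger x in LPS).
    Mean cartilage thickness uses the skeleton-sampled doubled distance
    transform; the coverage ratio compares axial-projection footprints of
    tibial cartilage and menisci.
    """
    for m in (cartilages, menisci):
        if not check_aligned(bones, m):
            raise ValueError("knee masks must share one grid")
    femur = bones.binary(femur_label)
    tibia = bones.binary(tibia_label)
    if not femur.any() or not tibia.any():
        raise ValueError("femur and tibia are required for mJSW")
    sp = bones.spacing
    voxvol = bones.voxel_volume

    volumes: dict[str, float] = {}
    for lab in cartilages.labels:
        name = cartilages.label_names.get(int(lab), f"cartilage_{lab}")
        volumes[name] = float((cartilages.data == lab).sum() * voxvol)
    volumes["menisci"] = float(menisci.binary().sum() * voxvol)
    if damage is not None:
        volumes["cartilage_damage"] = float(damage.binary().sum() * voxvol)

    thickness = {
        cartilages.label_names.get(int(lab), f"cartilage_{lab}"):
            _mean_thickness(cartilages.data == lab, sp)
        for lab in cartilages.labels
    }

    fem_pts = _surface_points_mm(femur, sp)
    tib_pts = _surface_points_mm(tibia, sp)
    split_x = tib_pts[:, 0].mean()
    medial_positive = knee_side == "right"

    def side_pts(pts, medial: bool):
        hi = pts[:, 0] >= split_x
        take = hi if (medial == medial_positive) else ~hi
        return pts[take]

    mjsw_med = _min_distance(side_pts(fem_pts, True), side_pts(tib_pts, True))
    mjsw_lat = _min_distance(side_pts(fem_pts, False), side_pts(tib_pts, False))

    tib_cart = None
    for lab, name in cartilages.label_names.items():
        if "tibial" in name:
            tib_cart = cartilages.data == lab
    if tib_cart is None or not tib_cart.any():
        raise ValueError("tibial cartilage empty; coverage undefined")
    cart_fp = tib_cart.any(axis=0)
    men_fp = menisci.binary().any(axis=0)
    coverage = float((cart_fp & men_fp).sum() / cart_fp.sum())

    return KneeReport(volumes, thickness, mjsw_med, mjsw_lat, coverage,
                      extras={"knee_side": knee_side})
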