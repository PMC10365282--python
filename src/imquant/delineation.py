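"""Semi-automatic ROI delineation and the ROI modification toolset.

The interactive tool mimics a rectangle-plus-seeds workflow: a rectangle is
drawn around the target on one axial slice, Canny edges inside the
rectangle propose a boundary, one positive seed is placed at the centroid
of the proposed region and four negative seeds at the rectangle vertices.
Seed edits re-run a marker-controlled watershed on the gradient-magnitude
image, which is deterministic and honours both seed polarities: the
returned region always contains every positive seed pixel and never a
negative one. Slice-to-slice propagation grows the annotation through the
volume with a dilate-by-one / intensity-gate rule.

All 2D operations act on axial slices (``volume.data[slice_index]``),
with in-slice points given as ``(row, col)`` = ``(y, x)`` voxel indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import feature, filters, segmentation

from .grid import ImageVolume, LabelMask, check_aligned, resample

logger = logging.getLogger(__name__)

__all__ = [
    "Rectangle2D",
    "Seed",
    "CannySpec",
    "PropagationSpec",
    "canny_edges",
    "init_interactive",
    "update_with_seeds",
    "propagate_annotation",
    "morph_modify",
    "roi_boolean",
    "roi_separate",
    "roi_duplicate",
]


@dataclass(frozen=True)
class Rectangle2D:
    """Axis-aligned rectangle on one axial slice, corners in (row, col)."""

    slice_index: int
    corner_min: tuple[int, int]
    corner_max: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.corner_min[0] < self.corner_max[0]
                and self.corner_min[1] < self.corner_max[1]):
            raise ValueError("corner_min must be strictly below corner_max componentwise")

    @property
    def vertices(self) -> list[tuple[int, int]]:
        (r0, c0), (r1, c1) = self.corner_min, self.corner_max
        return [(r0, c0), (r0, c1), (r1, c0), (r1, c1)]

    def contains(self, point: tuple[int, int]) -> bool:
        (r0, c0), (r1, c1) = self.corner_min, self.corner_max
        return r0 <= point[0] <= r1 and c0 <= point[1] <= c1

    def crop(self, image: np.ndarray) -> np.ndarray:
        (r0, c0), (r1, c1) = self.corner_min, self.corner_max
        return image[r0:r1 + 1, c0:c1 + 1]


@dataclass(frozen=True)
class Seed:
    """A foreground (positive) or background (negative) control point."""

    position: tuple[int, int]  # (row, col) on the slice
    polarity: Literal["positive", "negative"]

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")


@dataclass(frozen=True)
class CannySpec:
    """Canny parameters; thresholds default to the 70th/90th percentile of
    the in-rectangle gradient magnitude when left unset (scale-free)."""

    gaussian_sigma: float = 1.0
    low_threshold: float | None = None
    high_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.low_threshold is not None and self.high_threshold is not None:
            if not 0 < self.low_threshold <= self.high_threshold:
                raise ValueError("need 0 < low_threshold <= high_threshold")
        elif (self.low_threshold is None) != (self.high_threshold is None):
            raise ValueError("set both thresholds or neither")


@dataclass(frozen=True)
class PropagationSpec:
    direction: Literal["up", "down", "both"] = "both"
    max_slices: int = 1000
    keep_component: Literal["all", "largest", "containing_previous_centroid"] = "largest"
    intensity_sd_gate: float = 3.0

    def __post_init__(self) -> None:
        if self.max_slices < 1:
            raise ValueError("max_slices must be >= 1")


def _resolve_thresholds(image: np.ndarray, spec: CannySpec) -> tuple[float, float]:
    if spec.low_threshold is not None:
        return spec.low_threshold, spec.high_threshold  # type: ignore[return-value]
    grad = filters.sobel(ndimage.gaussian_filter(image.astype(float), spec.gaussian_sigma))
    nz = grad[grad > 0]
    if nz.size == 0:
        return 1.0, 2.0  # flat image: any positive thresholds give no edges
    lo, hi = np.percentile(nz, [70.0, 90.0])
    if lo <= 0 or lo > hi:
        lo, hi = max(hi / 2, 1e-12), max(hi, 1e-12)
    return float(lo), float(hi)


def canny_edges(slice_image: np.ndarray, spec: CannySpec = CannySpec()) -> np.ndarray:
    """Thin hysteresis-thresholded edge map of one 2D slice."""
    slice_image = np.asarray(slice_image, dtype=float)
    if slice_image.ndim != 2 or min(slice_image.shape) < 3:
        raise ValueError("slice must be 2D and at least 3x3")
    lo, hi = _resolve_thresholds(slice_image, spec)
    return feature.canny(slice_image, sigma=spec.gaussian_sigma,
                         low_threshold=lo, high_threshold=hi)


def update_with_seeds(slice_image: np.ndarray, rect: Rectangle2D,
                      seeds: Sequence[Seed],
                      gaussian_sigma: float = 1.0) -> np.ndarray:
    """Marker-controlled watershed segmentation driven by seed polarity.

    Positive seeds are foreground markers; negative seeds and the rectangle
    border are background markers. The watershed runs on the gradient
    magnitude of the smoothed in-rectangle image, so region boundaries lock
    onto intensity edges.
    """
    slice_image = np.asarray(slice_image, dtype=float)
    positives = [s for s in seeds if s.polarity == "positive"]
    if not positives:
        raise ValueError("at least one positive seed is required")
    for s in seeds:
        if not rect.contains(s.position):
            raise ValueError(f"seed {s.position} outside the rectangle")

    sub = rect.crop(slice_image)
    grad = filters.sobel(ndimage.gaussian_filter(sub, gaussian_sigma))
    markers = np.zeros(sub.shape, dtype=np.int32)
    markers[0, :] = markers[-1, :] = markers[:, 0] = markers[:, -1] = 1
    (r0, c0) = rect.corner_min
    for s in seeds:
        rr, cc = s.position[0] - r0, s.position[1] - c0
        markers[rr, cc] = 1 if s.polarity == "negative" else 2
    labels = segmentation.watershed(grad, markers)
    mask = np.zeros(slice_image.shape, dtype=bool)
    mask[r0:rect.corner_max[0] + 1, c0:rect.corner_max[1] + 1] = labels == 2
    return mask


def init_interactive(slice_image: np.ndarray, rect: Rectangle2D,
                     spec: CannySpec = CannySpec()) -> tuple[np.ndarray, list[Seed]]:
    """Rectangle-initialized segmentation: Canny boundary, then auto-seeds.

    Returns the segmented mask and the generated seeds — exactly one
    positive seed at the centroid of the Canny-proposed region and four
    negative seeds at the rectangle vertices. With no edges inside the
    rectangle the mask is empty (a warning is logged) but seeds are still
    returned so the user can continue interactively.
    """
    slice_image = np.asarray(slice_image, dtype=float)
    sub = rect.crop(slice_image)
    if min(sub.shape) < 5:
        raise ValueError("rectangle must cover at least 5x5 pixels")
    edges = canny_edges(sub, spec)
    negatives = [Seed(v, "negative") for v in rect.vertices]
    (r0, c0) = rect.corner_min
    if not edges.any():
        logger.warning("no edges detected inside the rectangle; returning empty mask")
        centre = ((rect.corner_min[0] + rect.corner_max[0]) // 2,
                  (rect.corner_min[1] + rect.corner_max[1]) // 2)
        return np.zeros(slice_image.shape, dtype=bool), [Seed(centre, "positive")] + negatives

    region = ndimage.binary_fill_holes(edges)
    rr, cc = np.nonzero(region)
    centroid = (int(round(rr.mean())) + r0, int(round(cc.mean())) + c0)
    seeds = [Seed(centroid, "positive")] + negatives
    mask = update_with_seeds(slice_image, rect, seeds, gaussian_sigma=spec.gaussian_sigma)
    return mask, seeds


def propagate_annotation(volume: ImageVolume, mask_slice: np.ndarray,
                         slice_index: int,
                         spec: PropagationSpec = PropagationSpec()) -> LabelMask:
    """Propagate a single-slice annotation through adjacent slices.

    For each successive slice the previous mask is dilated by one voxel and
    intersected with pixels whose intensity lies within mean +/- k*sd of the
    previous mask's intensities (statistics refreshed each slice), then
    filtered per ``keep_component``. Propagation halts on an empty candidate
    or after ``max_slices`` steps per direction.
    """
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if not mask_slice.any():
        raise ValueError("initial mask slice is empty")
    if mask_slice.shape != volume.data.shape[1:]:
        raise ValueError("mask slice shape does not match the volume slice")

    out = np.zeros(volume.shape, dtype=np.int16)
    out[slice_index] = mask_slice

    def step(prev_mask: np.ndarray, z: int) -> np.ndarray:
        prev_vals = volume.data[z_prev[0]][prev_mask]
        mu, sd = float(prev_vals.mean()), float(prev_vals.std())
        gate = spec.intensity_sd_gate * max(sd, 1e-9)
        cand = ndimage.binary_dilation(prev_mask, iterations=1)
        sl = volume.data[z]
        cand &= np.abs(sl - mu) <= gate
        if not cand.any():
            return cand
        if spec.keep_component == "all":
            return cand
        lab, n = ndimage.label(cand)
        if n <= 1:
            return cand
        if spec.keep_component == "largest":
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            return lab == (int(np.argmax(sizes)) + 1)
        # containing_previous_centroid
        rr, cc = np.nonzero(prev_mask)
        cr, cc_ = int(round(rr.mean())), int(round(cc.mean()))
        keep = lab[cr, cc_]
        if keep == 0:  # centroid fell outside; fall back to largest
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
        return lab == keep

    directions = []
    if spec.direction in ("up", "both"):
        directions.append(+1)
    if spec.direction in ("down", "both"):
        directions.append(-1)
    for d in directions:
        prev = mask_slice
        z_prev = [slice_index]
        z = slice_index + d
        steps = 0
        while 0 <= z < volume.shape[0] and steps < spec.max_slices:
            cur = step(prev, z)
            if not cur.any():
                break
            out[z] = cur
            prev, z_prev[0] = cur, z
            z += d
            steps += 1
    return LabelMask(out, volume.spacing, volume.origin, volume.direction,
                     label_names={1: "propagated"})


# ---------------------------------------------------------------------------
# ROI modification
# ---------------------------------------------------------------------------

def morph_modify(mask: LabelMask, mode: Literal["dilate", "erode"],
                 distances_mm) -> LabelMask:
    """Dilate or erode the (binarized) ROI by per-axis distances in mm.

    The structuring element is an ellipsoid with the given semi-axes in
    world mm, realised by thresholding the exact Euclidean distance
    transform in the ellipsoid-scaled metric — so anisotropic spacing
    behaves isotropically in physical space and no integer-radius rounding
    inflates the result. Zero distances on all axes are the identity.
    """
    distances_mm = tuple(float(d) for d in distances_mm)
    if any(d < 0 for d in distances_mm):
        raise ValueError("distances must be non-negative")
    if mode not in ("dilate", "erode"):
        raise ValueError("mode must be dilate or erode")
    binary = mask.binary()
    if all(d == 0 for d in distances_mm):
        out = binary
    else:
        # sampling in ellipsoid units: voxel step (mm) / semi-axis (mm);
        # a zero distance makes that axis infinitely "far" (no effect)
        sampling = [s / d if d > 0 else 1e9
                    for s, d in zip(mask.spacing[::-1], distances_mm[::-1])]
        if mode == "dilate":
            out = binary | (ndimage.distance_transform_edt(~binary, sampling=sampling) <= 1.0)
        else:
            out = ndimage.distance_transform_edt(binary, sampling=sampling) > 1.0
            if binary.any() and not out.any():
                logger.warning("erosion by %s mm emptied the mask", distances_mm)
    return LabelMask(out.astype(np.int16), mask.spacing, mask.origin,
                     mask.direction, label_names={1: "roi"})


def roi_boolean(masks: Sequence[LabelMask],
                op: Literal["union", "intersection", "complement"]) -> LabelMask:
    """Voxelwise set algebra on nonzero voxels of co-registered masks.

    ``complement`` takes exactly two masks and returns A minus B.
    """
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0]
    for m in masks[1:]:
        if not check_aligned(ref, m):
            raise ValueError("masks are not on identical grids")
    bins = [m.binary() for m in masks]
    if op == "union":
        out = np.logical_or.reduce(bins)
    elif op == "intersection":
        out = np.logical_and.reduce(bins)
    elif op == "complement":
        if len(masks) != 2:
            raise ValueError("complement takes exactly 2 masks (A minus B)")
        out = bins[0] & ~bins[1]
    else:
        raise ValueError(f"unknown op {op!r}")
    return LabelMask(out.astype(np.int16), ref.spacing, ref.origin,
                     ref.direction, label_names={1: op})


_CONN_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def roi_separate(mask: LabelMask, volume: ImageVolume | None = None,
                 by: Literal["intensity_intervals", "connectivity", "min_size"] = "connectivity",
                 intervals: Sequence[float] | None = None,
                 connectivity: int = 26,
                 min_size: int = 1) -> LabelMask:
    """Split an ROI into labeled parts by intensity, connectivity or size."""
    binary = mask.binary()
    if by == "intensity_intervals":
        if volume is None:
            raise ValueError("intensity_intervals requires an aligned volume")
        if not check_aligned(volume, mask):
            raise ValueError("volume and mask grids differ")
        if intervals is None or list(intervals) != sorted(intervals):
            raise ValueError("intervals must be a sorted boundary list")
        out = np.zeros(mask.shape, dtype=np.int16)
        # interval k: (b[k-1], b[k]]; below first boundary -> 1, above last -> len+1
        out[binary] = np.searchsorted(np.asarray(intervals, dtype=float),
                                      volume.data[binary], side="left") + 1
    elif by == "connectivity":
        if connectivity not in _CONN_STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")
        out, _ = ndimage.label(binary, structure=_CONN_STRUCTURES[connectivity])
        out = out.astype(np.int16)
    elif by == "min_size":
        if min_size < 1:
            raise ValueError("min_size must be >= 1")
        lab, n = ndimage.label(binary, structure=_CONN_STRUCTURES[26])
        out = np.zeros(mask.shape, dtype=np.int16)
        next_id = 0
        for i in range(1, n + 1):
            comp = lab == i
            if comp.sum() >= min_size:
                next_id += 1
                out[comp] = next_id
    else:
        raise ValueError(f"unknown separation mode {by!r}")
    return LabelMask(out, mask.spacing, mask.origin, mask.direction)


def roi_duplicate(mask: LabelMask, target_grid: ImageVolume) -> LabelMask:
    """Transfer an ROI onto another grid via world coordinates (nearest)."""
    src_lo = np.asarray(mask.origin) - np.asarray(mask.spacing)
    src_hi = mask.world_coordinates(np.asarray(mask.shape) - 1) + np.asarray(mask.spacing)
    tgt_lo = np.asarray(target_grid.origin) - np.asarray(target_grid.spacing)
    tgt_hi = (target_grid.world_coordinates(np.asarray(target_grid.shape) - 1)
              + np.asarray(target_grid.spacing))
    lo = np.maximum(np.minimum(src_lo, src_hi), np.minimum(tgt_lo, tgt_hi))
    hi = np.minimum(np.maximum(src_lo, src_hi), np.maximum(tgt_lo, tgt_hi))
    if np.any(hi <= lo):
        raise ValueError("source mask and target grid do not overlap in world space")

    import SimpleITK as sitk

    res = sitk.Resample(
        sitk.Cast(mask.to_sitk(), sitk.sitkInt32),
        target_grid.to_sitk(),
        sitk.Transform(),
        sitk.sitkNearestNeighbor,
        0,
        sitk.sitkInt32,
    )
    out = LabelMask.from_sitk(res)
    out.label_names = dict(mask.label_names)
    return out
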