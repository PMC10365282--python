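"""Image and mask data model with standard-format I/O and grid operations.

Volumes are stored as numpy arrays indexed ``[z, y, x]`` (slice-major, as
returned by ``SimpleITK.GetArrayFromImage``), while the grid metadata —
``spacing``, ``origin`` and ``direction`` — follows the DICOM/ITK world
convention: per-component order ``(x, y, z)`` in millimetres, LPS world
frame, direction as a 3x3 orthonormal matrix whose columns are the world
directions of the x/y/z image axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "LabelMask",
    "NormalizationSpec",
    "DiscretizationSpec",
    "read_volume",
    "write_volume",
    "resample",
    "normalize_intensity",
    "discretize_fixed_bins",
    "check_aligned",
]

_ALIGN_RTOL = 1e-4


def _as_tuple3(v) -> tuple[float, float, float]:
    a = tuple(float(x) for x in np.asarray(v).ravel())
    if len(a) != 3:
        raise ValueError(f"expected 3 components, got {len(a)}")
    return a  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid with world metadata.

    Parameters
    ----------
    data
        3D array indexed ``[z, y, x]``; intensities in HU or arbitrary units.
    spacing
        Voxel size per world axis ``(x, y, z)``, mm; all components > 0.
    origin
        World coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal matrix; columns are world directions of image axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite (found NaN/inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid_as(self, other: "ImageVolume | LabelMask") -> bool:
        return check_aligned(self, other)

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data)
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(tuple(self.direction.ravel()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(
            data=sitk.GetArrayFromImage(img),
            spacing=img.GetSpacing(),
            origin=img.GetOrigin(),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)

    def world_coordinates(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Map integer (or fractional) ``[z, y, x]`` indices to world mm."""
        idx_xyz = np.asarray(indices_zyx, dtype=float)[..., ::-1]
        scaled = idx_xyz * np.asarray(self.spacing)
        return scaled @ self.direction.T + np.asarray(self.origin)


@dataclass
class LabelMask(ImageVolume):
    """A non-negative integer label volume; label 0 is background."""

    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data).astype(np.int32)
            if not np.allclose(self.data, as_int):
                raise ValueError("mask values must be integers")
            self.data = as_int
        if self.data.min() < 0:
            raise ValueError("mask labels must be non-negative")
        super().__post_init__()

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present."""
        u = np.unique(self.data)
        return u[u > 0]

    def binary(self, label: int | None = None) -> np.ndarray:
        """Boolean foreground: any nonzero voxel, or a single label."""
        if label is None:
            return self.data > 0
        return self.data == label

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "LabelMask":
        arr = sitk.GetArrayFromImage(img)
        return cls(
            data=np.rint(arr).astype(np.int32),
            spacing=img.GetSpacing(),
            origin=img.GetOrigin(),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )


@dataclass(frozen=True)
class NormalizationSpec:
    """Intensity normalization: ``mean_std``, ``max_min`` or ``center_width``.

    ``center_width`` clips to the window ``[center - width/2, center + width/2]``
    and maps that window affinely onto [0, 1]; ``width`` must be positive and
    there are no defaults — the window is acquisition-specific.
    """

    method: Literal["mean_std", "max_min", "center_width"]
    center: float | None = None
    width: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("mean_std", "max_min", "center_width"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.method == "center_width":
            if self.center is None or self.width is None:
                raise ValueError("center_width requires center and width")
            if self.width <= 0:
                raise ValueError("width must be > 0")


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin-number gray-level discretization (default 64 bins)."""

    bin_count: int = 64

    def __post_init__(self) -> None:
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, format: Literal["nifti", "dicom_series"] = "nifti",
                as_mask: bool = False) -> ImageVolume | LabelMask:
    """Read a NIfTI file or a DICOM series directory into a volume.

    DICOM slices are sorted into a single 3D volume by the series reader;
    a series with inconsistent spacing or orientation raises ``ValueError``
    naming the inconsistency.
    """
    path = Path(path)
    if format == "nifti":
        if not path.exists():
            raise FileNotFoundError(path)
        img = sitk.ReadImage(str(path))
    elif format == "dicom_series":
        if not path.is_dir():
            raise FileNotFoundError(f"DICOM series directory not found: {path}")
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise ValueError(f"no DICOM series found in {path}")
        _check_series_consistency(files)
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        raise ValueError(f"unknown format {format!r}")
    if img.GetDimension() == 2:  # single slice treated as a 1-slice volume
        img = sitk.JoinSeries(img)
    vol = (LabelMask if as_mask else ImageVolume).from_sitk(img)
    logger.info("read %s: shape=%s spacing=%s", path, vol.shape, vol.spacing)
    return vol


def _check_series_consistency(files) -> None:
    import pydicom

    orientations, spacings = [], []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        orientations.append(tuple(float(v) for v in ds.ImageOrientationPatient))
        spacings.append(tuple(float(v) for v in ds.PixelSpacing))
    if len(set(orientations)) > 1:
        raise ValueError("inconsistent DICOM series: mixed ImageOrientationPatient across slices")
    if len(set(spacings)) > 1:
        raise ValueError("inconsistent DICOM series: mixed PixelSpacing across slices")


def write_volume(volume: ImageVolume | LabelMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI; round-trips values and grid exactly."""
    path = Path(path)
    if np.issubdtype(volume.data.dtype, np.floating) and not np.isfinite(volume.data).all():
        raise ValueError("refusing to write non-finite intensities")
    path.parent.mkdir(parents=True, exist_ok=True)
    img = volume.to_sitk()
    sitk.WriteImage(img, str(path))
    logger.info("wrote %s: shape=%s spacing=%s", path, volume.shape, volume.spacing)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERPOLATORS = {
    "nearest": sitk.sitkNearestNeighbor,
    "linear": sitk.sitkLinear,
    "bspline": sitk.sitkBSpline,
}


def resample(volume: ImageVolume | LabelMask,
             target_spacing,
             interpolation: Literal["nearest", "linear", "bspline"] = "linear"):
    """Resample to ``target_spacing`` (x, y, z mm), preserving world extent.

    Output size per axis is ``round(n * s_in / s_out)`` (minimum 1) and the
    grid stays anchored at the input origin. Label masks must use nearest
    interpolation — anything else would invent labels.
    """
    target_spacing = _as_tuple3(target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    is_mask = isinstance(volume, LabelMask)
    if is_mask and interpolation != "nearest":
        raise ValueError("label masks must be resampled with nearest interpolation")
    if interpolation not in _INTERPOLATORS:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    size_xyz = volume.shape[::-1]
    new_size = [max(1, int(round(n * s_in / s_out)))
                for n, s_in, s_out in zip(size_xyz, volume.spacing, target_spacing)]
    img = volume.to_sitk()
    if is_mask:
        img = sitk.Cast(img, sitk.sitkInt32)
    res = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        _INTERPOLATORS[interpolation],
        volume.origin,
        target_spacing,
        tuple(volume.direction.ravel()),
        0,
        img.GetPixelID(),
    )
    out = type(volume).from_sitk(res)
    if is_mask:
        out.label_names = dict(volume.label_names)  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Intensity normalization and discretization
# ---------------------------------------------------------------------------

def normalize_intensity(volume: ImageVolume, spec: NormalizationSpec) -> ImageVolume:
    """Apply one of the supported whole-volume intensity normalizations."""
    x = volume.data.astype(float)
    if spec.method == "mean_std":
        sd = x.std()
        if sd == 0:
            raise ValueError("mean_std normalization undefined for constant volume")
        out = (x - x.mean()) / sd
    elif spec.method == "max_min":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("max_min normalization undefined for constant volume")
        out = (x - lo) / (hi - lo)
    else:  # center_width
        lo = spec.center - spec.width / 2.0  # type: ignore[operator]
        hi = spec.center + spec.width / 2.0  # type: ignore[operator]
        out = (np.clip(x, lo, hi) - lo) / (hi - lo)
    return ImageVolume(out, volume.spacing, volume.origin, volume.direction)


def discretize_fixed_bins(values, spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Fixed-bin-number discretization into integer bins 1..bin_count.

    ``bin(x) = floor(N * (x - min) / (max - min)) + 1`` with the maximum
    assigned bin N; a constant input collapses to bin 1 so that texture
    matrices stay defined on degenerate ROIs.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot discretize an empty value list")
    lo, hi = values.min(), values.max()
    n = spec.bin_count
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    bins = np.floor(n * (values - lo) / (hi - lo)).astype(np.int64) + 1
    return np.minimum(bins, n)


def check_aligned(volume: ImageVolume, mask: ImageVolume | LabelMask,
                  rtol: float = _ALIGN_RTOL) -> bool:
    """True iff shapes match and spacing/origin/direction agree within rtol."""
    if volume.shape != mask.shape:
        return False
    atol = rtol  # absolute fallback for components near zero (origin at 0)
    return (
        np.allclose(volume.spacing, mask.spacing, rtol=rtol, atol=atol)
        and np.allclose(volume.origin, mask.origin, rtol=rtol, atol=atol)
        and np.allclose(volume.direction, mask.direction, rtol=rtol, atol=atol)
    )
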