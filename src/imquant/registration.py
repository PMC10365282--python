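"""Classical rigid/affine registration and similarity metrics.

The similarity metrics (mean squared difference, normalized correlation,
mutual information) are computed directly from voxel arrays; optimization
of rigid/affine transforms runs through SimpleITK's multi-resolution
registration framework with centre-of-mass initialization. A hybrid loss
evaluates a *given* dense deformation field as a weighted sum of image
dissimilarity, a diffusion (squared spatial gradient) regularizer on the
displacement, and segmentation dissimilarity (1 - Dice); NC and MI enter
the loss negated so every term is a dissimilarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .grid import ImageVolume, LabelMask, check_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "AffineTransform3D",
    "DeformationField",
    "SimilaritySpec",
    "HybridLossSpec",
    "similarity",
    "register_linear",
    "apply_transform",
    "hybrid_loss",
    "dice",
]


@dataclass
class AffineTransform3D:
    """World-coordinate linear map ``x -> matrix @ (x - center) + center + translation``."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray
    kind: str = "affine"  # "rigid" | "affine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).ravel()
        self.center = np.asarray(self.center, dtype=float).ravel()
        if self.kind == "rigid":
            if not np.allclose(self.matrix @ self.matrix.T, np.eye(3), atol=1e-5):
                raise ValueError("rigid transform requires an orthonormal matrix")
            if np.linalg.det(self.matrix) < 0:
                raise ValueError("rigid transform requires determinant +1")

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.matrix.ravel()))
        t.SetCenter(tuple(self.center))
        t.SetTranslation(tuple(self.translation))
        return t

    @classmethod
    def from_sitk(cls, t, kind: str = "affine") -> "AffineTransform3D":
        m = np.asarray(t.GetMatrix()).reshape(3, 3)
        k = "rigid" if isinstance(t, sitk.Euler3DTransform) else kind
        return cls(m, t.GetTranslation(), t.GetCenter(), k)

    def inverse(self) -> "AffineTransform3D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform3D(inv, -inv @ self.translation, self.center, self.kind)

    @property
    def rotation_angles_deg(self) -> np.ndarray:
        """Euler angles (x, y, z, degrees) of the rotation part."""
        e = sitk.Euler3DTransform()
        e.SetMatrix(tuple(self.matrix.ravel()), 1e-6)
        return np.degrees([e.GetAngleX(), e.GetAngleY(), e.GetAngleZ()])

    def save(self, path) -> None:
        h = np.eye(4)
        h[:3, :3] = self.matrix
        # homogeneous form of the centered transform
        h[:3, 3] = self.translation + self.center - self.matrix @ self.center
        np.savetxt(path, h, header=f"kind: {self.kind} (4x4 homogeneous, world mm)")


@dataclass
class DeformationField:
    """Per-voxel displacement (mm, world components x/y/z) on the fixed grid."""

    displacements: np.ndarray  # shape (nz, ny, nx, 3), components (x, y, z)
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacement grid must have shape (nz, ny, nx, 3)")
        if not np.isfinite(self.displacements).all():
            raise ValueError("displacements must be finite")


@dataclass(frozen=True)
class SimilaritySpec:
    metric: str = "MSD"  # MSD | NC | MI
    mi_bins: int = 32

    def __post_init__(self) -> None:
        if self.metric not in ("MSD", "NC", "MI"):
            raise ValueError("metric must be MSD, NC or MI")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


@dataclass(frozen=True)
class HybridLossSpec:
    w_img: float = 1.0
    w_reg: float = 1.0
    w_seg: float = 1.0
    image_metric: SimilaritySpec = SimilaritySpec("MSD")

    def __post_init__(self) -> None:
        if min(self.w_img, self.w_reg, self.w_seg) < 0:
            raise ValueError("weights must be non-negative")
        if self.w_img == self.w_reg == self.w_seg == 0:
            raise ValueError("at least one weight must be positive")


def similarity(fixed: ImageVolume, moving: ImageVolume,
               spec: SimilaritySpec = SimilaritySpec()) -> float:
    """MSD, NC (Pearson) or MI (nats, joint histogram) on a shared grid."""
    if fixed.shape != moving.shape:
        raise ValueError("images must share a grid; resample first")
    a = fixed.data.astype(float).ravel()
    b = moving.data.astype(float).ravel()
    if spec.metric == "MSD":
        return float(((a - b) ** 2).mean())
    if spec.metric == "NC":
        if a.std() == 0 or b.std() == 0:
            raise ValueError("normalized correlation undefined for constant image")
        return float(np.corrcoef(a, b)[0, 1])
    joint, _, _ = np.histogram2d(a, b, bins=spec.mi_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


_SITK_INTERP = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear,
                "bspline": sitk.sitkBSpline}


def register_linear(fixed: ImageVolume, moving: ImageVolume,
                    kind: str = "rigid",
                    spec: SimilaritySpec = SimilaritySpec("MSD"),
                    levels: int = 3, seed: int = 0) -> AffineTransform3D:
    """Multi-resolution rigid/affine registration of ``moving`` to ``fixed``.

    Coarse-to-fine over ``levels`` octaves; the optimizer minimizes MSD or
    the negated NC/MI. Deterministic given the seed (used for MI sampling).
    """
    if kind not in ("rigid", "affine"):
        raise ValueError("kind must be rigid or affine")
    f = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    m = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)

    init = (sitk.Euler3DTransform() if kind == "rigid" else sitk.AffineTransform(3))
    init = sitk.CenteredTransformInitializer(
        f, m, init, sitk.CenteredTransformInitializerFilter.MOMENTS)

    reg = sitk.ImageRegistrationMethod()
    if spec.metric == "MSD":
        reg.SetMetricAsMeanSquares()
    elif spec.metric == "NC":
        reg.SetMetricAsCorrelation()
    else:
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=spec.mi_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=300,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2**i for i in range(levels - 1, -1, -1)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, s // 2) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(init, inPlace=False)

    result = reg.Execute(f, m)
    if isinstance(result, sitk.CompositeTransform):
        result = result.GetNthTransform(result.GetNumberOfTransforms() - 1)
    logger.info("registration stop: %s (metric %.6g)",
                reg.GetOptimizerStopConditionDescription(), reg.GetMetricValue())
    if kind == "rigid":
        e = sitk.Euler3DTransform(result)
        return AffineTransform3D(np.asarray(e.GetMatrix()).reshape(3, 3),
                                 e.GetTranslation(), e.GetCenter(), "rigid")
    a = sitk.AffineTransform(result)
    return AffineTransform3D(np.asarray(a.GetMatrix()).reshape(3, 3),
                             a.GetTranslation(), a.GetCenter(), "affine")


def apply_transform(moving: ImageVolume | LabelMask,
                    transform: AffineTransform3D,
                    reference: ImageVolume,
                    interpolation: str = "linear"):
    """Resample ``moving`` onto the reference grid under the transform."""
    if np.linalg.det(transform.matrix) == 0:
        raise ValueError("singular transform matrix")
    is_mask = isinstance(moving, LabelMask)
    if is_mask and interpolation != "nearest":
        interpolation = "nearest"
    img = moving.to_sitk()
    if is_mask:
        img = sitk.Cast(img, sitk.sitkInt32)
    res = sitk.Resample(img, reference.to_sitk(), transform.to_sitk(),
                        _SITK_INTERP[interpolation], 0.0)
    out = type(moving).from_sitk(res)
    if is_mask:
        out.label_names = dict(moving.label_names)
    return out


def dice(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of binarized masks."""
    aa = a.binary() if isinstance(a, LabelMask) else np.asarray(a, dtype=bool)
    bb = b.binary() if isinstance(b, LabelMask) else np.asarray(b, dtype=bool)
    denom = aa.sum() + bb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (aa & bb).sum() / denom)


def _warp_with_field(moving: ImageVolume, field: DeformationField,
                     reference: ImageVolume, interpolation: str) -> np.ndarray:
    disp = sitk.GetImageFromArray(field.displacements, isVector=True)
    disp.CopyInformation(reference.to_sitk())
    disp = sitk.Cast(disp, sitk.sitkVectorFloat64)
    tx = sitk.DisplacementFieldTransform(disp)
    img = moving.to_sitk()
    res = sitk.Resample(img, reference.to_sitk(), tx, _SITK_INTERP[interpolation], 0.0)
    return sitk.GetArrayFromImage(res)


def _diffusion_regularizer(field: DeformationField) -> float:
    """Mean squared spatial gradient of the displacement (all components)."""
    g_total = 0.0
    sp_zyx = field.spacing[::-1]
    for c in range(3):
        comp = field.displacements[..., c]
        grads = np.gradient(comp, *sp_zyx)
        g_total += sum(float((g**2).mean()) for g in grads)
    return g_total / 3.0


def hybrid_loss(fixed: ImageVolume, moving: ImageVolume, field: DeformationField,
                fixed_seg: LabelMask, moving_seg: LabelMask,
                spec: HybridLossSpec = HybridLossSpec()) -> tuple[float, dict[str, float]]:
    """Evaluate the hybrid registration loss for a supplied deformation.

    ``total = w_img * D_img(fixed, warp(moving)) + w_reg * R(field)
    + w_seg * (1 - Dice(fixed_seg, warp(moving_seg)))`` where R is the
    diffusion regularizer. Components are returned unweighted.
    """
    if fixed.shape != moving.shape or field.displacements.shape[:3] != fixed.shape:
        raise ValueError("fixed, moving and field grids must match")
    if fixed_seg.shape != fixed.shape or moving_seg.shape != fixed.shape:
        raise ValueError("segmentation grids must match the fixed image")

    warped = fixed.with_data(_warp_with_field(moving, field, fixed, "linear"))
    d = similarity(fixed, warped, spec.image_metric)
    if spec.image_metric.metric in ("NC", "MI"):
        d = -d  # dissimilarity orientation
    r = _diffusion_regularizer(field)
    warped_seg_arr = _warp_with_field(moving_seg, field, fixed, "nearest")
    s = 1.0 - dice(fixed_seg.binary(), warped_seg_arr > 0)
    total = spec.w_img * d + spec.w_reg * r + spec.w_seg * s
    return float(total), {"image": float(d), "regularizer": float(r), "segmentation": float(s)}
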