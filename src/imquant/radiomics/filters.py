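"""The 24-filter derived-image bank.

Smoothing / noise / sharpening filters run through SimpleITK; the eight
wavelet bands come from a single-level undecimated (stationary) 3D coiflet-1
decomposition so every derived image stays on the input grid. Noise filters
are deterministic given their seed. Unstated parameters are fixed package
defaults: 3x3x3 kernels for the box/mean filters, 1 binomial repetition,
5 curvature-flow iterations at step 0.05, 1 mm Gaussian sigma, unit
Laplacian-sharpening weight, and noise amplitude at 10% of the image
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
import SimpleITK as sitk

from ..grid import ImageVolume
from .registry import FILTER_NAMES

__all__ = ["FilterSpec", "apply_filter", "NOISE_FILTERS"]

NOISE_FILTERS = ("additive_gaussian_noise", "speckle_noise", "shot_noise")

WAVELET = "coif1"


@dataclass(frozen=True)
class FilterSpec:
    """A named derived-image filter with optional parameters and seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.name not in FILTER_NAMES:
            raise ValueError(f"unknown filter {self.name!r}; valid: {FILTER_NAMES}")
        if self.name in NOISE_FILTERS and self.seed is None:
            raise ValueError(f"filter {self.name!r} requires a seed")


def _wavelet_band(data: np.ndarray, band: str) -> np.ndarray:
    """One band of a single-level stationary 3D wavelet transform.

    ``band`` is e.g. ``"LLH"`` ordered (x, y, z); pywt's axis keys are in
    array order (z, y, x) with 'a'=low pass and 'd'=high pass.
    """
    key = "".join("a" if b == "L" else "d" for b in band[::-1])
    # swtn needs every axis length divisible by 2: pad symmetrically, crop back
    pads = [(0, (-s) % 2) for s in data.shape]
    padded = np.pad(data, pads, mode="symmetric")
    coeffs = pywt.swtn(padded, WAVELET, level=1, norm=True)[0]
    out = coeffs[key]
    return out[: data.shape[0], : data.shape[1], : data.shape[2]]


def apply_filter(volume: ImageVolume, spec: FilterSpec) -> ImageVolume:
    """Apply one of the 24 derived-image filters; output keeps the grid."""
    name = spec.name
    p = spec.params
    if name.startswith("wavelet_"):
        out = _wavelet_band(volume.data.astype(float), name.split("_")[1])
        return volume.with_data(out)

    img = sitk.Cast(volume.to_sitk(), sitk.sitkFloat64)
    if name == "box_mean":
        res = sitk.BoxMean(img, [int(p.get("radius", 1))] * 3)
    elif name == "box_sigma":
        res = sitk.BoxSigma(img, [int(p.get("radius", 1))] * 3)
    elif name == "mean":
        res = sitk.Mean(img, [int(p.get("radius", 1))] * 3)
    elif name == "binomial_blur":
        res = sitk.BinomialBlur(img, int(p.get("repetitions", 1)))
    elif name == "curvature_flow":
        res = sitk.CurvatureFlow(img, timeStep=float(p.get("time_step", 0.05)),
                                 numberOfIterations=int(p.get("iterations", 5)))
    elif name == "normalize":
        res = sitk.Normalize(img)
    elif name == "laplacian_sharpening":
        res = sitk.LaplacianSharpening(img)
    elif name == "discrete_gaussian":
        sigma = float(p.get("sigma_mm", 1.0))
        res = sitk.DiscreteGaussian(img, variance=sigma**2)
    elif name == "recursive_gaussian":
        res = sitk.SmoothingRecursiveGaussian(img, sigma=float(p.get("sigma_mm", 1.0)))
    elif name.startswith("log_sigma_"):
        sigma = float(name.removeprefix("log_sigma_"))
        res = sitk.LaplacianRecursiveGaussian(img, sigma=sigma)
    elif name in NOISE_FILTERS:
        sd = float(volume.data.std())
        amp = float(p.get("amplitude", 0.1)) * (sd if sd > 0 else 1.0)
        if name == "additive_gaussian_noise":
            f = sitk.AdditiveGaussianNoiseImageFilter()
            f.SetStandardDeviation(amp)
            f.SetMean(0.0)
        elif name == "speckle_noise":
            f = sitk.SpeckleNoiseImageFilter()
            f.SetStandardDeviation(float(p.get("amplitude", 0.1)))
        else:  # shot_noise
            f = sitk.ShotNoiseImageFilter()
            f.SetScale(float(p.get("scale", 1.0)))
        f.SetSeed(int(spec.seed))  # type: ignore[arg-type]
        res = f.Execute(img)
    else:  # pragma: no cover — names are validated in FilterSpec
        raise ValueError(f"unhandled filter {name!r}")
    return ImageVolume.from_sitk(res)
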