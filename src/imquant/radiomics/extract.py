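"""Whole-inventory feature extraction for one ROI."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..grid import (DiscretizationSpec, ImageVolume, LabelMask,
                    NormalizationSpec, check_aligned, normalize_intensity,
                    resample)
from .filters import NOISE_FILTERS, FilterSpec, apply_filter
from .firstorder import first_order_features
from .registry import FeatureRegistry, build_registry
from .shape import shape_features
from .texture import texture_features

logger = logging.getLogger(__name__)

__all__ = ["ExtractionSettings", "FeatureVector", "extract_all", "features_to_frame"]


@dataclass(frozen=True)
class ExtractionSettings:
    """Preprocessing applied before feature computation.

    Resampling (when requested) is applied to image and mask alike (linear
    vs nearest); normalization precedes filtering; discretization uses a
    fixed bin number (64 by default) per derived image.
    """

    normalization: NormalizationSpec | None = None
    target_spacing: tuple[float, float, float] | None = None
    discretization: DiscretizationSpec = DiscretizationSpec()


@dataclass
class FeatureVector:
    """Extraction result: one value per registry definition plus provenance."""

    values: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values)


def extract_all(volume: ImageVolume, mask: LabelMask,
                registry: FeatureRegistry | None = None,
                settings: ExtractionSettings = ExtractionSettings(),
                seed: int = 0) -> FeatureVector:
    """Extract every registry feature from one ROI.

    Shape features are computed once from the preprocessed mask geometry;
    first-order and texture features are computed on the original image and
    on each derived image the registry references. Noise filters derive
    their per-filter seed from ``seed`` so the call is reproducible.
    """
    if registry is None:
        registry = build_registry(enable_filters=True)
    if not check_aligned(volume, mask):
        raise ValueError("volume and mask are not on the same grid")
    if settings.normalization is not None:
        volume = normalize_intensity(volume, settings.normalization)
    if settings.target_spacing is not None:
        volume = resample(volume, settings.target_spacing, "linear")
        mask = resample(mask, settings.target_spacing, "nearest")
        if not mask.binary().any():
            raise ValueError("ROI vanished after resampling to "
                             f"{settings.target_spacing} mm")

    spec = settings.discretization
    voxvol = volume.voxel_volume
    sources = registry.sources
    needed_families = {
        src: {d.family for d in registry if d.image_source == src} for src in sources
    }

    values: dict[str, float] = {}
    filter_seeds: dict[str, int] = {}
    rng = np.random.default_rng(seed)
    for src in sources:
        if src == "original":
            img = volume
        else:
            fseed = None
            if src in NOISE_FILTERS:
                fseed = int(rng.integers(1, 2**31 - 1))
                filter_seeds[src] = fseed
            img = apply_filter(volume, FilterSpec(src, seed=fseed))
        fams = needed_families[src]
        if "first_order" in fams:
            fo = first_order_features(img.data[mask.binary()], voxvol, spec)
            for k, v in fo.items():
                values[f"{src}_first_order_{k}"] = v
        if "shape" in fams:
            for k, v in shape_features(mask).items():
                values[f"{src}_shape_{k}"] = v
        if fams & {"glcm", "glrlm", "glszm", "ngtdm", "gldm"}:
            tex = texture_features(img, mask, spec)
            for fam in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
                if fam in fams:
                    for k, v in tex[fam].items():
                        values[f"{src}_{fam}_{k}"] = v

    ordered = {d.key: values[d.key] for d in registry}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        logger.warning("non-finite features replaced by 0: %s", bad[:5])
        for k in bad:
            ordered[k] = 0.0
    prov = {
        "normalization": settings.normalization.method if settings.normalization else None,
        "target_spacing": settings.target_spacing,
        "bin_count": spec.bin_count,
        "seed": seed,
        "filter_seeds": filter_seeds,
    }
    return FeatureVector(ordered, prov)


def features_to_frame(vectors: dict[str, FeatureVector]) -> pd.DataFrame:
    """Stack named feature vectors into a table (one row per ROI)."""
    return pd.DataFrame({name: fv.values for name, fv in vectors.items()}).T
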