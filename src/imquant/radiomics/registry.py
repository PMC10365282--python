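"""The feature inventory: 104 original-image features plus 24 derived images.

The registry enumerates every feature the engine computes: on the original
image 18 first-order, 14 shape and 72 texture features (21 GLCM, 16 GLRLM,
16 GLSZM, 5 NGTDM, 14 GLDM), and on each of 24 filtered images the 18
first-order plus 72 texture features (shape is geometry-only and is not
repeated per derived image). Total: 104 + 24 * 90 = 2,264.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FeatureDefinition",
    "FeatureRegistry",
    "build_registry",
    "FIRST_ORDER_FEATURES",
    "SHAPE_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "GLDM_FEATURES",
    "FILTER_NAMES",
    "FAMILY_FEATURES",
]

FIRST_ORDER_FEATURES = (
    "energy", "total_energy", "entropy", "minimum", "percentile_10",
    "percentile_90", "maximum", "mean", "median", "interquartile_range",
    "range", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_squared", "skewness", "kurtosis", "variance", "uniformity",
)

SHAPE_FEATURES = (
    "mesh_volume", "voxel_volume", "surface_area", "surface_volume_ratio",
    "sphericity", "maximum_3d_diameter", "maximum_2d_diameter_slice",
    "maximum_2d_diameter_column", "maximum_2d_diameter_row",
    "major_axis_length", "minor_axis_length", "least_axis_length",
    "elongation", "flatness",
)

GLCM_FEATURES = (
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "joint_energy",
    "joint_entropy", "imc1", "imc2", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance",
    "maximum_probability", "sum_of_squares",
)

GLRLM_FEATURES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "run_length_nonuniformity",
    "run_length_nonuniformity_normalized", "run_percentage",
    "gray_level_variance", "run_variance", "run_entropy",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
)

GLSZM_FEATURES = (
    "small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized", "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized", "zone_percentage",
    "gray_level_variance", "zone_variance", "zone_entropy",
    "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

GLDM_FEATURES = (
    "small_dependence_emphasis", "large_dependence_emphasis",
    "gray_level_nonuniformity", "dependence_nonuniformity",
    "dependence_nonuniformity_normalized", "gray_level_variance",
    "dependence_variance", "dependence_entropy", "low_gray_level_emphasis",
    "high_gray_level_emphasis", "small_dependence_low_gray_level_emphasis",
    "small_dependence_high_gray_level_emphasis",
    "large_dependence_low_gray_level_emphasis",
    "large_dependence_high_gray_level_emphasis",
)

FAMILY_FEATURES: dict[str, tuple[str, ...]] = {
    "first_order": FIRST_ORDER_FEATURES,
    "shape": SHAPE_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "gldm": GLDM_FEATURES,
}

TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

FILTER_NAMES = (
    "box_mean", "additive_gaussian_noise", "binomial_blur", "curvature_flow",
    "box_sigma", "normalize", "laplacian_sharpening", "discrete_gaussian",
    "mean", "speckle_noise", "recursive_gaussian", "shot_noise",
    "log_sigma_0.5", "log_sigma_1", "log_sigma_1.5", "log_sigma_2",
    "wavelet_LLL", "wavelet_LLH", "wavelet_LHL", "wavelet_LHH",
    "wavelet_HLL", "wavelet_HLH", "wavelet_HHL", "wavelet_HHH",
)


@dataclass(frozen=True)
class FeatureDefinition:
    """One entry of the inventory: (family, image source, feature name)."""

    family: str
    image_source: str  # "original" or a filter name
    feature_name: str

    def __post_init__(self) -> None:
        if self.family not in FAMILY_FEATURES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "shape" and self.image_source != "original":
            raise ValueError("shape features exist only on the original image")
        if self.image_source != "original" and self.image_source not in FILTER_NAMES:
            raise ValueError(f"unknown image source {self.image_source!r}")

    @property
    def key(self) -> str:
        return f"{self.image_source}_{self.family}_{self.feature_name}"


@dataclass
class FeatureRegistry:
    """Ordered feature inventory with per-family and per-source counts."""

    definitions: list[FeatureDefinition] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    @property
    def keys(self) -> list[str]:
        return [d.key for d in self.definitions]

    def count_by_family(self, source: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.definitions:
            if source is not None and d.image_source != source:
                continue
            counts[d.family] = counts.get(d.family, 0) + 1
        return counts

    def count_by_source(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.definitions:
            counts[d.image_source] = counts.get(d.image_source, 0) + 1
        return counts

    @property
    def sources(self) -> list[str]:
        seen: list[str] = []
        for d in self.definitions:
            if d.image_source not in seen:
                seen.append(d.image_source)
        return seen


def build_registry(enable_filters: bool = True) -> FeatureRegistry:
    """Enumerate the feature inventory.

    With filters enabled the registry holds 2,264 definitions (104 on the
    original image and 90 on each of the 24 derived images); with filters
    disabled, the 104 original-image definitions only.
    """
    defs: list[FeatureDefinition] = []
    for fam in ("first_order", "shape", *TEXTURE_FAMILIES):
        for name in FAMILY_FEATURES[fam]:
            defs.append(FeatureDefinition(fam, "original", name))
    if enable_filters:
        for src in FILTER_NAMES:
            for fam in ("first_order", *TEXTURE_FAMILIES):
                for name in FAMILY_FEATURES[fam]:
                    defs.append(FeatureDefinition(fam, src, name))
    if len({d.key for d in defs}) != len(defs):
        raise RuntimeError("duplicate feature definitions in registry")
    return FeatureRegistry(defs)
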