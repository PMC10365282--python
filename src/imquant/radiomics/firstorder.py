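"""First-order (intensity histogram) statistics of an ROI.

Eighteen features over the raw ROI intensities; ``entropy`` and
``uniformity`` use the fixed-bin-number discretized histogram (base-2 log),
``total_energy`` scales ``energy`` by the voxel volume. Moments are
population moments (no small-sample correction); on a constant ROI the
skewness and kurtosis, which have 0/0 form, are returned as 0.
"""

from __future__ import annotations

import numpy as np

from ..grid import DiscretizationSpec, discretize_fixed_bins

__all__ = ["first_order_features"]


def first_order_features(values, voxel_volume_mm3: float = 1.0,
                         spec: DiscretizationSpec = DiscretizationSpec()) -> dict[str, float]:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]

    bins = discretize_fixed_bins(x, spec)
    p = np.bincount(bins)[1:].astype(float)
    p = p[p > 0] / n

    return {
        "energy": float((x**2).sum()),
        "total_energy": float(voxel_volume_mm3 * (x**2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "minimum": float(x.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "maximum": float(x.max()),
        "mean": float(mean),
        "median": float(np.median(x)),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": float(np.abs(inner - inner.mean()).mean()),
        "root_mean_squared": float(np.sqrt((x**2).mean())),
        "skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "variance": float(m2),
        "uniformity": float((p**2).sum()),
    }
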