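"""Gray-level texture matrices and their features.

All five families operate on the fixed-bin-number discretized ROI:

* GLCM — symmetric co-occurrences at Chebyshev distance 1, accumulated per
  direction over the 13 unique 3D offsets; features are computed per
  direction and averaged.
* GLRLM — maximal same-bin collinear runs, per direction (13, averaged).
* GLSZM — 26-connected same-bin zones; a single matrix, no directions.
* NGTDM — per-level summed absolute difference between a voxel's bin and
  the mean bin of its valid 26-neighbours.
* GLDM — per-voxel dependence = number of 26-neighbours with the same bin
  (dependence tolerance alpha = 0); matrix over (level, dependence + 1).

Feature definitions follow the standard IBSI formulations with base-2
logarithms. Degenerate 0/0 forms (e.g. GLCM correlation on a single-level
ROI) return 0 so that feature vectors stay finite.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import ndimage

from ..grid import DiscretizationSpec, ImageVolume, LabelMask, discretize_fixed_bins

logger = logging.getLogger(__name__)

__all__ = [
    "OFFSETS_13",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "texture_features",
]

# the 13 unique 3D directions at Chebyshev distance 1 (one per +/- pair)
OFFSETS_13 = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3)
    if off != (0, 0, 0) and (off > (0, 0, 0))
)
OFFSETS_26 = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


def _binned(volume: ImageVolume, mask: LabelMask,
            spec: DiscretizationSpec) -> np.ndarray:
    """Discretized ROI as a 3D int array; 0 marks outside-ROI voxels."""
    roi = mask.binary()
    if not roi.any():
        raise ValueError("empty ROI")
    bins = np.zeros(volume.shape, dtype=np.int64)
    bins[roi] = discretize_fixed_bins(volume.data[roi], spec)
    return bins


def _shifted_views(a: np.ndarray, off) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (a[v], a[v + off]) over the in-bounds overlap."""
    sl_a, sl_b = [], []
    for d, n in zip(off, a.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return a[tuple(sl_a)], a[tuple(sl_b)]


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(bins: np.ndarray, levels: np.ndarray, off) -> np.ndarray:
    a, b = _shifted_views(bins, off)
    valid = (a > 0) & (b > 0)
    ia = np.searchsorted(levels, a[valid])
    ib = np.searchsorted(levels, b[valid])
    ng = len(levels)
    m = np.zeros((ng, ng))
    np.add.at(m, (ia, ib), 1.0)
    np.add.at(m, (ib, ia), 1.0)
    return m


def _glcm_features_one(P: np.ndarray, v: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs in this direction")
    p = P / total
    ng = len(v)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    vi = v[:, None].astype(float)
    vj = v[None, :].astype(float)
    mu_x = float((px * v).sum())
    mu_y = float((py * v).sum())
    sig_x = float(np.sqrt((px * (v - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (v - mu_y) ** 2).sum()))

    diff = np.abs(vi - vj)
    kmax = int(diff.max())
    p_diff = np.array([p[diff == k].sum() for k in range(kmax + 1)])
    ks = np.arange(kmax + 1, dtype=float)
    da = float((ks * p_diff).sum())

    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = px[:, None] * py[None, :]
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(np.maximum(pxy[nz], 1e-300))).sum())
    hxy2 = _entropy2(pxy.ravel())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    corr = (
        float(((vi * vj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
        if sig_x > 0 and sig_y > 0 else 0.0
    )
    offdiag = diff > 0
    inv_var = float((p[offdiag] / diff[offdiag] ** 2).sum()) if offdiag.any() else 0.0

    return {
        "autocorrelation": float((vi * vj * p).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float(((vi + vj - mu_x - mu_y) ** 4 * p).sum()),
        "cluster_shade": float(((vi + vj - mu_x - mu_y) ** 3 * p).sum()),
        "cluster_tendency": float(((vi + vj - mu_x - mu_y) ** 2 * p).sum()),
        "contrast": float(((vi - vj) ** 2 * p).sum()),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": _entropy2(p_diff),
        "difference_variance": float(((ks - da) ** 2 * p_diff).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference": float((p / (1.0 + diff)).sum()),
        "inverse_difference_normalized": float((p / (1.0 + diff / ng)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "inverse_difference_moment_normalized": float((p / (1.0 + diff**2 / ng**2)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "sum_of_squares": float((px * (v - mu_x) ** 2).sum()),
    }


def glcm_features(volume: ImageVolume, mask: LabelMask,
                  spec: DiscretizationSpec = DiscretizationSpec()) -> dict[str, float]:
    """21 co-occurrence features, averaged over the 13 directions."""
    bins = _binned(volume, mask, spec)
    if (bins > 0).sum() < 2:
        raise ValueError("GLCM requires at least 2 ROI voxels")
    levels = np.unique(bins[bins > 0])
    per_dir = []
    for off in OFFSETS_13:
        m = _glcm_matrix(bins, levels, off)
        if m.sum() > 0:
            per_dir.append(_glcm_features_one(m, levels))
    if not per_dir:
        raise ValueError("ROI has no neighbouring voxel pairs")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _runs_one_direction(bins: np.ndarray, off) -> list[tuple[int, int]]:
    """(level, length) of every maximal same-bin run along ``off``."""
    d = np.asarray(off)
    shape = np.asarray(bins.shape)
    idx = np.argwhere(bins > 0)
    prev = idx - d
    inb = ((prev >= 0) & (prev < shape)).all(axis=1)
    starts_mask = np.ones(len(idx), dtype=bool)
    pi = prev[inb]
    same = (bins[pi[:, 0], pi[:, 1], pi[:, 2]]
            == bins[idx[inb][:, 0], idx[inb][:, 1], idx[inb][:, 2]])
    keep = np.nonzero(inb)[0][same]
    starts_mask[keep] = False
    runs = []
    for s in idx[starts_mask]:
        lvl = bins[tuple(s)]
        length = 1
        nxt = s + d
        while (nxt >= 0).all() and (nxt < shape).all() and bins[tuple(nxt)] == lvl:
            length += 1
            nxt = nxt + d
        runs.append((int(lvl), length))
    return runs


def _sz_features(counts: dict[tuple[int, int], float], n_voxels: int,
                 names: tuple[str, str, str, str, str, str, str]) -> dict[str, float]:
    """Shared run-length / zone-size / dependence feature formulas.

    ``counts`` maps (gray level, size) -> count; ``names`` supplies the
    family-specific feature names in the order (small, large, size-nonunif,
    size-nonunif-normalized, percentage, size-variance, size-entropy).
    """
    if not counts:
        raise ValueError("empty texture matrix")
    items = np.array([(i, j, c) for (i, j), c in counts.items() if c > 0], dtype=float)
    i, j, c = items[:, 0], items[:, 1], items[:, 2]
    ns = c.sum()
    p = c / ns
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()

    def by(key):
        out: dict[float, float] = {}
        for k, cc in zip(key, c):
            out[k] = out.get(k, 0.0) + cc
        return np.array(list(out.values()))

    small, large, nonunif, nonunif_n, pct, var, ent = names
    feats = {
        small: float((c / j**2).sum() / ns),
        large: float((c * j**2).sum() / ns),
        "gray_level_nonuniformity": float((by(i) ** 2).sum() / ns),
        "gray_level_nonuniformity_normalized": float((by(i) ** 2).sum() / ns**2),
        nonunif: float((by(j) ** 2).sum() / ns),
        nonunif_n: float((by(j) ** 2).sum() / ns**2),
        pct: float(ns / n_voxels),
        "gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
        var: float((p * (j - mu_j) ** 2).sum()),
        ent: _entropy2(p),
        "low_gray_level": float((c / i**2).sum() / ns),
        "high_gray_level": float((c * i**2).sum() / ns),
        "small_low": float((c / (i**2 * j**2)).sum() / ns),
        "small_high": float((c * i**2 / j**2).sum() / ns),
        "large_low": float((c * j**2 / i**2).sum() / ns),
        "large_high": float((c * i**2 * j**2).sum() / ns),
    }
    return feats


_GLRLM_NAMES = ("short_run_emphasis", "long_run_emphasis",
                "run_length_nonuniformity", "run_length_nonuniformity_normalized",
                "run_percentage", "run_variance", "run_entropy")
_GLRLM_RENAME = {
    "low_gray_level": "low_gray_level_run_emphasis",
    "high_gray_level": "high_gray_level_run_emphasis",
    "small_low": "short_run_low_gray_level_emphasis",
    "small_high": "short_run_high_gray_level_emphasis",
    "large_low": "long_run_low_gray_level_emphasis",
    "large_high": "long_run_high_gray_level_emphasis",
}


def glrlm_features(volume: ImageVolume, mask: LabelMask,
                   spec: DiscretizationSpec = DiscretizationSpec()) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    bins = _binned(volume, mask, spec)
    n_voxels = int((bins > 0).sum())
    per_dir = []
    for off in OFFSETS_13:
        counts: dict[tuple[int, int], float] = {}
        for lvl, length in _runs_one_direction(bins, off):
            counts[(lvl, length)] = counts.get((lvl, length), 0.0) + 1.0
        f = _sz_features(counts, n_voxels, _GLRLM_NAMES)
        per_dir.append({_GLRLM_RENAME.get(k, k): val for k, val in f.items()})
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_GLSZM_NAMES = ("small_area_emphasis", "large_area_emphasis",
                "size_zone_nonuniformity", "size_zone_nonuniformity_normalized",
                "zone_percentage", "zone_variance", "zone_entropy")
_GLSZM_RENAME = {
    "low_gray_level": "low_gray_level_zone_emphasis",
    "high_gray_level": "high_gray_level_zone_emphasis",
    "small_low": "small_area_low_gray_level_emphasis",
    "small_high": "small_area_high_gray_level_emphasis",
    "large_low": "large_area_low_gray_level_emphasis",
    "large_high": "large_area_high_gray_level_emphasis",
}


def glszm_features(volume: ImageVolume, mask: LabelMask,
                   spec: DiscretizationSpec = DiscretizationSpec()) -> dict[str, float]:
    """16 size-zone features from 26-connected same-bin zones (one matrix)."""
    bins = _binned(volume, mask, spec)
    n_voxels = int((bins > 0).sum())
    counts: dict[tuple[int, int], float] = {}
    for lvl in np.unique(bins[bins > 0]):
        lab, n = ndimage.label(bins == lvl, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        for s in np.asarray(sizes, dtype=int):
            counts[(int(lvl), int(s))] = counts.get((int(lvl), int(s)), 0.0) + 1.0
    f = _sz_features(counts, n_voxels, _GLSZM_NAMES)
    return {_GLSZM_RENAME.get(k, k): v for k, v in f.items()}


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(volume: ImageVolume, mask: LabelMask,
                   spec: DiscretizationSpec = DiscretizationSpec()) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength."""
    bins = _binned(volume, mask, spec)
    roi = bins > 0
    nb_sum = np.zeros(bins.shape)
    nb_cnt = np.zeros(bins.shape)
    for off in OFFSETS_26:
        src, dst = _shift_slices(bins.shape, off)
        nb = bins[src]
        ok = nb > 0
        nb_sum[dst] += np.where(ok, nb, 0).astype(float)
        nb_cnt[dst] += ok.astype(float)

    valid = roi & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("no ROI voxel has a valid neighbour")
    mean_nb = np.zeros(bins.shape)
    mean_nb[valid] = nb_sum[valid] / nb_cnt[valid]

    levels = np.unique(bins[roi])
    n_i = np.array([float((valid & (bins == l)).sum()) for l in levels])
    s_i = np.array([
        float(np.abs(l - mean_nb[valid & (bins == l)]).sum()) for l in levels
    ])
    n_total = n_i.sum()
    p_i = n_i / n_total
    nz = p_i > 0
    ngp = int(nz.sum())
    v = levels.astype(float)

    coarseness = float(1.0 / (p_i * s_i).sum()) if (p_i * s_i).sum() > 0 else 1e6
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[nz], p_i[nz], indexing="ij")
        vi_, vj_ = np.meshgrid(v[nz], v[nz], indexing="ij")
        contrast = float(
            (pi_ * pj_ * (vi_ - vj_) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / n_total
        )
        denom = np.abs(vi_ * pi_ - vj_ * pj_).sum()
        busyness = float((p_i * s_i).sum() / denom) if denom > 0 else 0.0
        si_, sj_ = np.meshgrid(s_i[nz], s_i[nz], indexing="ij")
        complexity = float(
            (np.abs(vi_ - vj_) * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)).sum() / n_total
        )
        strength = (
            float(((pi_ + pj_) * (vi_ - vj_) ** 2).sum() / s_i.sum())
            if s_i.sum() > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def _shift_slices(shape, off):
    """(source, destination) slice tuples so that dst voxels read their
    neighbour at +off (i.e. ``bins[dst + off] == bins[src]`` alignment)."""
    src, dst = [], []
    for d, n in zip(off, shape):
        if d >= 0:
            src.append(slice(d, n))
            dst.append(slice(0, n - d))
        else:
            src.append(slice(0, n + d))
            dst.append(slice(-d, n))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

_GLDM_NAMES = ("small_dependence_emphasis", "large_dependence_emphasis",
               "dependence_nonuniformity", "dependence_nonuniformity_normalized",
               "_drop_percentage", "dependence_variance", "dependence_entropy")
_GLDM_RENAME = {
    "low_gray_level": "low_gray_level_emphasis",
    "high_gray_level": "high_gray_level_emphasis",
    "small_low": "small_dependence_low_gray_level_emphasis",
    "small_high": "small_dependence_high_gray_level_emphasis",
    "large_low": "large_dependence_low_gray_level_emphasis",
    "large_high": "large_dependence_high_gray_level_emphasis",
}


def gldm_features(volume: ImageVolume, mask: LabelMask,
                  spec: DiscretizationSpec = DiscretizationSpec(),
                  alpha: int = 0) -> dict[str, float]:
    """14 dependence features; dependence counts same-bin 26-neighbours."""
    bins = _binned(volume, mask, spec)
    roi = bins > 0
    dep = np.zeros(bins.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = _shift_slices(bins.shape, off)
        nb = bins[src]
        here = bins[dst]
        dep[dst] += ((nb > 0) & (here > 0) & (np.abs(nb - here) <= alpha)).astype(np.int64)
    counts: dict[tuple[int, int], float] = {}
    lv = bins[roi]
    dv = dep[roi] + 1  # dependence j = neighbour count + 1
    for l, j in zip(lv, dv):
        counts[(int(l), int(j))] = counts.get((int(l), int(j)), 0.0) + 1.0
    f = _sz_features(counts, int(roi.sum()), _GLDM_NAMES)
    f.pop("_drop_percentage")  # dependence counts cover every voxel; no percentage feature
    f.pop("gray_level_nonuniformity_normalized")
    return {_GLDM_RENAME.get(k, k): v for k, v in f.items()}


def texture_features(volume: ImageVolume, mask: LabelMask,
                     spec: DiscretizationSpec = DiscretizationSpec()) -> dict[str, dict[str, float]]:
    """All five texture families on one (volume, mask) pair."""
    return {
        "glcm": glcm_features(volume, mask, spec),
        "glrlm": glrlm_features(volume, mask, spec),
        "glszm": glszm_features(volume, mask, spec),
        "ngtdm": ngtdm_features(volume, mask, spec),
        "gldm": gldm_features(volume, mask, spec),
    }
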