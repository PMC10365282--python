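"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops straight from the definitions —
no shared code with the package implementation — so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3)
           if d != (0, 0, 0) and d > (0, 0, 0)]
DIRS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def discretize(values: np.ndarray, nbins: int) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=int)
    out = np.empty(values.shape, dtype=int)
    flat = values.ravel()
    res = []
    for x in flat:
        b = math.floor(nbins * (x - lo) / (hi - lo)) + 1
        res.append(min(b, nbins))
    return np.array(res).reshape(values.shape)


def binned_roi(volume: np.ndarray, roi: np.ndarray, nbins: int) -> np.ndarray:
    bins = np.zeros(volume.shape, dtype=int)
    vals = volume[roi]
    bins[roi] = discretize(vals, nbins)
    return bins


def _inb(p, shape):
    return all(0 <= p[i] < shape[i] for i in range(3))


def _xlog2(p):
    return p * math.log2(p) if p > 0 else 0.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_oracle(bins: np.ndarray) -> dict[str, float]:
    levels = sorted(int(v) for v in np.unique(bins[bins > 0]))
    idx = {v: i for i, v in enumerate(levels)}
    ng = len(levels)
    per_dir = []
    for d in DIRS_13:
        P = np.zeros((ng, ng))
        for p in np.argwhere(bins > 0):
            q = p + d
            if _inb(q, bins.shape) and bins[tuple(q)] > 0:
                P[idx[bins[tuple(p)]], idx[bins[tuple(q)]]] += 1
                P[idx[bins[tuple(q)]], idx[bins[tuple(p)]]] += 1
        if P.sum() == 0:
            continue
        per_dir.append(_glcm_feats(P / P.sum(), levels))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _glcm_feats(p: np.ndarray, levels) -> dict[str, float]:
    ng = len(levels)
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mux = sum(levels[i] * px[i] for i in range(ng))
    muy = sum(levels[j] * py[j] for j in range(ng))
    sx = math.sqrt(sum(px[i] * (levels[i] - mux) ** 2 for i in range(ng)))
    sy = math.sqrt(sum(py[j] * (levels[j] - muy) ** 2 for j in range(ng)))
    f = {}
    f["autocorrelation"] = sum(levels[i] * levels[j] * p[i][j]
                               for i in range(ng) for j in range(ng))
    f["joint_average"] = mux
    for name, power in (("cluster_prominence", 4), ("cluster_shade", 3),
                        ("cluster_tendency", 2)):
        f[name] = sum((levels[i] + levels[j] - mux - muy) ** power * p[i][j]
                      for i in range(ng) for j in range(ng))
    f["contrast"] = sum((levels[i] - levels[j]) ** 2 * p[i][j]
                        for i in range(ng) for j in range(ng))
    if sx > 0 and sy > 0:
        f["correlation"] = (f["autocorrelation"] - mux * muy) / (sx * sy)
    else:
        f["correlation"] = 0.0
    kmax = max(abs(levels[i] - levels[j]) for i in range(ng) for j in range(ng))
    pdiff = [0.0] * (kmax + 1)
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(levels[i] - levels[j])] += p[i][j]
    da = sum(k * pdiff[k] for k in range(kmax + 1))
    f["difference_average"] = da
    f["difference_entropy"] = -sum(_xlog2(q) for q in pdiff)
    f["difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in range(kmax + 1))
    f["joint_energy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(_xlog2(p[i][j]) for i in range(ng) for j in range(ng))
    f["joint_entropy"] = hxy
    hx = -sum(_xlog2(q) for q in px)
    hy = -sum(_xlog2(q) for q in py)
    hxy1 = -sum(p[i][j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if p[i][j] > 0)
    hxy2 = -sum(_xlog2(px[i] * py[j]) for i in range(ng) for j in range(ng))
    f["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["imc2"] = (math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
                 if hxy2 >= hxy else 0.0)
    f["inverse_difference"] = sum(p[i][j] / (1 + abs(levels[i] - levels[j]))
                                  for i in range(ng) for j in range(ng))
    f["inverse_difference_normalized"] = sum(
        p[i][j] / (1 + abs(levels[i] - levels[j]) / ng)
        for i in range(ng) for j in range(ng))
    f["inverse_difference_moment"] = sum(
        p[i][j] / (1 + (levels[i] - levels[j]) ** 2)
        for i in range(ng) for j in range(ng))
    f["inverse_difference_moment_normalized"] = sum(
        p[i][j] / (1 + (levels[i] - levels[j]) ** 2 / ng**2)
        for i in range(ng) for j in range(ng))
    f["inverse_variance"] = sum(p[i][j] / (levels[i] - levels[j]) ** 2
                                for i in range(ng) for j in range(ng) if i != j
                                and levels[i] != levels[j])
    f["maximum_probability"] = p.max()
    f["sum_of_squares"] = sum(px[i] * (levels[i] - mux) ** 2 for i in range(ng))
    return f


# ---------------------------------------------------------------------------
# shared run/zone/dependence formula block
# ---------------------------------------------------------------------------

def _matrix_feats(entries: list[tuple[int, int, float]], n_voxels: int) -> dict[str, float]:
    """entries: (gray level i, size j, count). Generic 16-feature block."""
    ns = sum(c for _, _, c in entries)
    f = {}
    f["small"] = sum(c / j**2 for _, j, c in entries) / ns
    f["large"] = sum(c * j**2 for _, j, c in entries) / ns
    gl = {}
    sz = {}
    for i, j, c in entries:
        gl[i] = gl.get(i, 0.0) + c
        sz[j] = sz.get(j, 0.0) + c
    f["gln"] = sum(v**2 for v in gl.values()) / ns
    f["glnn"] = sum(v**2 for v in gl.values()) / ns**2
    f["szn"] = sum(v**2 for v in sz.values()) / ns
    f["sznn"] = sum(v**2 for v in sz.values()) / ns**2
    f["pct"] = ns / n_voxels
    mui = sum(c * i for i, _, c in entries) / ns
    muj = sum(c * j for _, j, c in entries) / ns
    f["glv"] = sum(c * (i - mui) ** 2 for i, _, c in entries) / ns
    f["szv"] = sum(c * (j - muj) ** 2 for _, j, c in entries) / ns
    f["ent"] = -sum(_xlog2(c / ns) for _, _, c in entries)
    f["lgl"] = sum(c / i**2 for i, _, c in entries) / ns
    f["hgl"] = sum(c * i**2 for i, _, c in entries) / ns
    f["s_lgl"] = sum(c / (i**2 * j**2) for i, j, c in entries) / ns
    f["s_hgl"] = sum(c * i**2 / j**2 for i, j, c in entries) / ns
    f["l_lgl"] = sum(c * j**2 / i**2 for i, j, c in entries) / ns
    f["l_hgl"] = sum(c * i**2 * j**2 for i, j, c in entries) / ns
    return f


def glrlm_oracle(bins: np.ndarray) -> dict[str, float]:
    """Run-length features by explicit line scanning, averaged over directions."""
    shape = bins.shape
    n_vox = int((bins > 0).sum())
    per_dir = []
    for d in DIRS_13:
        counts: dict[tuple[int, int], float] = {}
        # entry points: voxels whose predecessor along d is out of the grid
        for p0 in itertools.product(*[range(s) for s in shape]):
            prev = tuple(p0[i] - d[i] for i in range(3))
            if _inb(prev, shape):
                continue
            # scan the line, run-length-encoding with ROI gaps as breaks
            seq = []
            p = p0
            while _inb(p, shape):
                seq.append(int(bins[p]))
                p = tuple(p[i] + d[i] for i in range(3))
            run_val, run_len = None, 0
            for v in seq + [0]:
                if v == run_val and v > 0:
                    run_len += 1
                else:
                    if run_val is not None and run_val > 0:
                        counts[(run_val, run_len)] = counts.get((run_val, run_len), 0.0) + 1
                    run_val, run_len = v, 1
        entries = [(i, j, c) for (i, j), c in counts.items()]
        g = _matrix_feats(entries, n_vox)
        per_dir.append({
            "short_run_emphasis": g["small"], "long_run_emphasis": g["large"],
            "gray_level_nonuniformity": g["gln"],
            "gray_level_nonuniformity_normalized": g["glnn"],
            "run_length_nonuniformity": g["szn"],
            "run_length_nonuniformity_normalized": g["sznn"],
            "run_percentage": g["pct"], "gray_level_variance": g["glv"],
            "run_variance": g["szv"], "run_entropy": g["ent"],
            "low_gray_level_run_emphasis": g["lgl"],
            "high_gray_level_run_emphasis": g["hgl"],
            "short_run_low_gray_level_emphasis": g["s_lgl"],
            "short_run_high_gray_level_emphasis": g["s_hgl"],
            "long_run_low_gray_level_emphasis": g["l_lgl"],
            "long_run_high_gray_level_emphasis": g["l_hgl"],
        })
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glszm_oracle(bins: np.ndarray) -> dict[str, float]:
    """Size-zone features via hand-rolled BFS flood fill (26-connected)."""
    n_vox = int((bins > 0).sum())
    seen = np.zeros(bins.shape, dtype=bool)
    counts: dict[tuple[int, int], float] = {}
    for p0 in map(tuple, np.argwhere(bins > 0)):
        if seen[p0]:
            continue
        lvl = int(bins[p0])
        stack = [p0]
        seen[p0] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in DIRS_26:
                q = tuple(p[i] + d[i] for i in range(3))
                if _inb(q, bins.shape) and not seen[q] and bins[q] == lvl:
                    seen[q] = True
                    stack.append(q)
        counts[(lvl, size)] = counts.get((lvl, size), 0.0) + 1
    g = _matrix_feats([(i, j, c) for (i, j), c in counts.items()], n_vox)
    return {
        "small_area_emphasis": g["small"], "large_area_emphasis": g["large"],
        "gray_level_nonuniformity": g["gln"],
        "gray_level_nonuniformity_normalized": g["glnn"],
        "size_zone_nonuniformity": g["szn"],
        "size_zone_nonuniformity_normalized": g["sznn"],
        "zone_percentage": g["pct"], "gray_level_variance": g["glv"],
        "zone_variance": g["szv"], "zone_entropy": g["ent"],
        "low_gray_level_zone_emphasis": g["lgl"],
        "high_gray_level_zone_emphasis": g["hgl"],
        "small_area_low_gray_level_emphasis": g["s_lgl"],
        "small_area_high_gray_level_emphasis": g["s_hgl"],
        "large_area_low_gray_level_emphasis": g["l_lgl"],
        "large_area_high_gray_level_emphasis": g["l_hgl"],
    }


def ngtdm_oracle(bins: np.ndarray) -> dict[str, float]:
    levels = sorted(int(v) for v in np.unique(bins[bins > 0]))
    n_i = {l: 0 for l in levels}
    s_i = {l: 0.0 for l in levels}
    for p in map(tuple, np.argwhere(bins > 0)):
        nb = []
        for d in DIRS_26:
            q = tuple(p[i] + d[i] for i in range(3))
            if _inb(q, bins.shape) and bins[q] > 0:
                nb.append(int(bins[q]))
        if not nb:
            continue
        l = int(bins[p])
        n_i[l] += 1
        s_i[l] += abs(l - sum(nb) / len(nb))
    n_tot = sum(n_i.values())
    p_i = {l: n_i[l] / n_tot for l in levels}
    act = [l for l in levels if p_i[l] > 0]
    ngp = len(act)
    ps = sum(p_i[l] * s_i[l] for l in levels)
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p_i[a] * p_i[b] * (a - b) ** 2 for a in act for b in act)
                    / (ngp * (ngp - 1))) * (sum(s_i.values()) / n_tot)
        denom = sum(abs(a * p_i[a] - b * p_i[b]) for a in act for b in act)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b])
                         / (p_i[a] + p_i[b]) for a in act for b in act) / n_tot
        stot = sum(s_i.values())
        strength = (sum((p_i[a] + p_i[b]) * (a - b) ** 2 for a in act for b in act)
                    / stot) if stot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complexity": complexity, "strength": strength}


def gldm_oracle(bins: np.ndarray, alpha: int = 0) -> dict[str, float]:
    counts: dict[tuple[int, int], float] = {}
    n_vox = int((bins > 0).sum())
    for p in map(tuple, np.argwhere(bins > 0)):
        dep = 0
        for d in DIRS_26:
            q = tuple(p[i] + d[i] for i in range(3))
            if _inb(q, bins.shape) and bins[q] > 0 and abs(int(bins[q]) - int(bins[p])) <= alpha:
                dep += 1
        key = (int(bins[p]), dep + 1)
        counts[key] = counts.get(key, 0.0) + 1
    g = _matrix_feats([(i, j, c) for (i, j), c in counts.items()], n_vox)
    return {
        "small_dependence_emphasis": g["small"],
        "large_dependence_emphasis": g["large"],
        "gray_level_nonuniformity": g["gln"],
        "dependence_nonuniformity": g["szn"],
        "dependence_nonuniformity_normalized": g["sznn"],
        "gray_level_variance": g["glv"], "dependence_variance": g["szv"],
        "dependence_entropy": g["ent"],
        "low_gray_level_emphasis": g["lgl"],
        "high_gray_level_emphasis": g["hgl"],
        "small_dependence_low_gray_level_emphasis": g["s_lgl"],
        "small_dependence_high_gray_level_emphasis": g["s_hgl"],
        "large_dependence_low_gray_level_emphasis": g["l_lgl"],
        "large_dependence_high_gray_level_emphasis": g["l_hgl"],
    }


# ---------------------------------------------------------------------------
# AUC by pair counting
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
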