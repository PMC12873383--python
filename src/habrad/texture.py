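"""Gray-level matrix and first-order texture features on 3-D regions.

All functions operate on an integer "level volume": a 3-D array with 0
outside the region and discretized gray levels 1..Ng inside.  Matrix
definitions follow the common radiomics (IBSI-style) formulations:

* GLCM — symmetric co-occurrence counts accumulated over the 13 unique
  3-D offsets at distance 1, normalised once over all directions.
* GLRLM — run counts accumulated over the 13 directions.
* GLSZM — 26-connected zones of equal level.
* GLDM — dependence size j = 1 + number of 26-neighbours within ``alpha``
  of the centre level (the centre voxel counts itself).
* NGTDM — per-level sums of |level - mean 26-neighbour level|, computed over
  voxels with at least one in-region neighbour.

Entropies are in bits (log base 2).  Degenerate inputs (constant region,
single-voxel region) follow explicit conventions noted per feature.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# the 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
OFFSETS_13 = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
)
OFFSETS_26 = tuple(
    (sx * o[0], sx * o[1], sx * o[2]) for o in OFFSETS_13 for sx in (1, -1)
)

_EPS = np.finfo(np.float64).tiny


def discretize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width discretization of ``values`` onto levels 1..n_levels.

    Bins span the input min-max; a constant input maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretize an empty input")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    width = (hi - lo) / n_levels
    lev = np.floor((values - lo) / width).astype(np.int64) + 1
    return np.clip(lev, 1, n_levels)


def _log2(p):
    return np.log2(p, out=np.zeros_like(p), where=p > 0)


def _entropy_bits(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _shifted_pairs(level_vol: np.ndarray, offset):
    """In-region (a, b) level pairs for one offset."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, level_vol.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    a = level_vol[tuple(sl_a)]
    b = level_vol[tuple(sl_b)]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def glcm_matrix(level_vol: np.ndarray, n_levels: int, distance: int = 1) -> np.ndarray:
    """Symmetric GLCM counts accumulated over the 13 directions."""
    mat = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in OFFSETS_13:
        scaled = tuple(d * distance for d in off)
        a, b = _shifted_pairs(level_vol, scaled)
        if a.size:
            np.add.at(mat, (a - 1, b - 1), 1.0)
            np.add.at(mat, (b - 1, a - 1), 1.0)
    return mat


def glrlm_matrix(level_vol: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts R(level, run_length) accumulated over 13 directions."""
    max_len = int(max(level_vol.shape))
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    region = level_vol > 0
    for off in OFFSETS_13:
        # run starts: in-region voxels whose predecessor along -off is not
        # the same level (or falls outside the array / region)
        prev_same = np.zeros(level_vol.shape, dtype=bool)
        same = _same_level(level_vol, off)
        prev_same[_dest_slice(level_vol.shape, off)] = same
        starts = np.argwhere(region & ~prev_same)
        if starts.size == 0:
            continue
        levels = level_vol[tuple(starts.T)]
        lengths = np.ones(len(starts), dtype=np.int64)
        cur = starts.copy()
        active = np.arange(len(starts))
        d = np.asarray(off)
        while active.size:
            nxt = cur[active] + d
            inb = np.all((nxt >= 0) & (nxt < level_vol.shape), axis=1)
            cont = np.zeros(len(active), dtype=bool)
            if inb.any():
                idx = nxt[inb]
                cont_vals = level_vol[tuple(idx.T)]
                cont[inb] = cont_vals == levels[active[inb]]
            lengths[active[cont]] += 1
            cur[active[cont]] += d
            active = active[cont]
        np.add.at(mat, (levels - 1, lengths - 1), 1.0)
    return mat


def _slices_pair(shape, offset):
    sl_a, sl_b = [], []
    for d, n in zip(offset, shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def _same_level(level_vol, offset):
    sl_a, sl_b = _slices_pair(level_vol.shape, offset)
    a = level_vol[sl_a]
    b = level_vol[sl_b]
    return (a > 0) & (a == b)


def _dest_slice(shape, offset):
    _, sl_b = _slices_pair(shape, offset)
    return sl_b


def glszm_matrix(level_vol: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts Z(level, zone_size) using 26-connectivity."""
    struct = np.ones((3, 3, 3), dtype=bool)
    max_size = int((level_vol > 0).sum())
    mat = np.zeros((n_levels, max(max_size, 1)), dtype=np.float64)
    for lvl in np.unique(level_vol[level_vol > 0]):
        lab, n = ndimage.label(level_vol == lvl, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            mat[lvl - 1, s - 1] += 1.0
    return mat


def gldm_matrix(level_vol: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts D(level, j); j = 1 + #26-neighbours within alpha."""
    region = level_vol > 0
    dep = np.zeros(level_vol.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sl_a, sl_b = _slices_pair(level_vol.shape, off)
        a = level_vol[sl_a]
        b = level_vol[sl_b]
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[sl_a] += ok
    mat = np.zeros((n_levels, 27), dtype=np.float64)
    levels = level_vol[region]
    np.add.at(mat, (levels - 1, dep[region]), 1.0)
    return mat


def ngtdm_table(level_vol: np.ndarray, n_levels: int):
    """Return (n_i, p_i, s_i) arrays over levels 1..n_levels.

    Only voxels with >= 1 in-region 26-neighbour contribute; ``n_i`` counts
    those voxels per level, ``s_i`` sums |level - mean neighbour level|.
    """
    region = level_vol > 0
    nb_sum = np.zeros(level_vol.shape, dtype=np.float64)
    nb_cnt = np.zeros(level_vol.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sl_a, sl_b = _slices_pair(level_vol.shape, off)
        b = level_vol[sl_b]
        ok = (level_vol[sl_a] > 0) & (b > 0)
        nb_sum[sl_a] += np.where(ok, b, 0)
        nb_cnt[sl_a] += ok
    valid = region & (nb_cnt > 0)
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    if valid.any():
        levels = level_vol[valid]
        diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
        np.add.at(n_i, levels - 1, 1.0)
        np.add.at(s_i, levels - 1, diffs)
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


# ---------------------------------------------------------------------------
# feature vectors per class
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(values: np.ndarray, voxel_volume: float,
                         n_levels: int = 32) -> dict[str, float]:
    """18 first-order statistics of raw region intensities.

    Skewness is Fisher skewness and Kurtosis is excess kurtosis, both defined
    as 0 for a constant region.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    mean = x.mean()
    var = x.var()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m2 = var
        m3 = ((x - mean) ** 3).mean()
        m4 = ((x - mean) ** 4).mean()
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2 - 3.0
    else:
        skew = kurt = 0.0
    levels = discretize(x, n_levels)
    p = np.bincount(levels, minlength=n_levels + 1)[1:] / n
    return {
        "Energy": float((x ** 2).sum()),
        "TotalEnergy": float(voxel_volume * (x ** 2).sum()),
        "Entropy": _entropy_bits(p),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((p ** 2).sum()),
    }


GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy",
    "MaximumProbability", "SumEntropy", "SumSquares",
)


def glcm_features(mat: np.ndarray) -> dict[str, float]:
    """22 features of a (possibly unnormalised) symmetric GLCM.

    Degenerate conventions for a single-cell matrix: entropies 0, Imc1/Imc2
    0, Correlation 0, InverseVariance 0 (the i = j term is excluded).
    """
    ng = mat.shape[0]
    total = mat.sum()
    if total == 0:
        return {name: 0.0 for name in GLCM_NAMES}
    p = mat / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    k_diff = np.arange(ng, dtype=np.float64)          # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.int64).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)  # i+j = 2..2ng
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(np.int64).ravel() - 2, p.ravel())

    da = float((k_diff * p_diff).sum())
    hxy = _entropy_bits(p.ravel())
    hx = _entropy_bits(px)
    outer = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-(p * _log2(outer))[(p > 0) & (outer > 0)].sum())
    hxy2 = _entropy_bits(outer.ravel())
    max_hx = hx  # symmetric matrix: HX == HY
    if max_hx > 0:
        imc1 = (hxy - hxy1) / max_hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0:
        corr = float(((ii - mu_x) * (jj - mu_x) * p).sum() / (sig_x * sig_x))
    else:
        corr = 0.0
    nz = k_diff >= 1
    inv_var = float((p_diff[nz] / k_diff[nz] ** 2).sum())
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float(((ii + jj - 2 * mu_x) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu_x) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu_x) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy_bits(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff ** 2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": _entropy_bits(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }


GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def glrlm_features(mat: np.ndarray, n_voxels: int, n_directions: int = 13
                   ) -> dict[str, float]:
    """16 run-length features of an accumulated run matrix R(level, length)."""
    nr = mat.sum()
    if nr == 0:
        return {name: 0.0 for name in GLRLM_NAMES}
    ng, nl = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    l = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    p = mat / nr
    r_i = mat.sum(axis=1)
    r_l = mat.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_l = float((l * p).sum())
    return {
        "GrayLevelNonUniformity": float((r_i ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((r_i ** 2).sum() / nr ** 2),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "HighGrayLevelRunEmphasis": float((mat * i ** 2).sum() / nr),
        "LongRunEmphasis": float((mat * l ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * i ** 2 * l ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * l ** 2 / i ** 2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((mat / i ** 2).sum() / nr),
        "RunEntropy": _entropy_bits(p.ravel()),
        "RunLengthNonUniformity": float((r_l ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((r_l ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / (n_voxels * n_directions)),
        "RunVariance": float(((l - mu_l) ** 2 * p).sum()),
        "ShortRunEmphasis": float((mat / l ** 2).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * i ** 2 / l ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (i ** 2 * l ** 2)).sum() / nr),
    }


GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """16 size-zone features of a zone matrix Z(level, size)."""
    nz = mat.sum()
    if nz == 0:
        return {name: 0.0 for name in GLSZM_NAMES}
    ng, ns = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    p = mat / nz
    z_i = mat.sum(axis=1)
    z_s = mat.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_s = float((s * p).sum())
    return {
        "GrayLevelNonUniformity": float((z_i ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((z_i ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "HighGrayLevelZoneEmphasis": float((mat * i ** 2).sum() / nz),
        "LargeAreaEmphasis": float((mat * s ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((mat * i ** 2 * s ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((mat * s ** 2 / i ** 2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((mat / i ** 2).sum() / nz),
        "SizeZoneNonUniformity": float((z_s ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((z_s ** 2).sum() / nz ** 2),
        "SmallAreaEmphasis": float((mat / s ** 2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((mat * i ** 2 / s ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((mat / (i ** 2 * s ** 2)).sum() / nz),
        "ZoneEntropy": _entropy_bits(p.ravel()),
        "ZonePercentage": float(nz / n_voxels),
        "ZoneVariance": float(((s - mu_s) ** 2 * p).sum()),
    }


GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)


def gldm_features(mat: np.ndarray) -> dict[str, float]:
    """14 dependence-matrix features of D(level, dependence_size)."""
    nd = mat.sum()
    if nd == 0:
        return {name: 0.0 for name in GLDM_NAMES}
    ng, nj = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nj + 1, dtype=np.float64)[None, :]
    p = mat / nd
    d_i = mat.sum(axis=1)
    d_j = mat.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    return {
        "DependenceEntropy": _entropy_bits(p.ravel()),
        "DependenceNonUniformity": float((d_j ** 2).sum() / nd),
        "DependenceNonUniformityNormalized": float((d_j ** 2).sum() / nd ** 2),
        "DependenceVariance": float(((j - mu_j) ** 2 * p).sum()),
        "GrayLevelNonUniformity": float((d_i ** 2).sum() / nd),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "HighGrayLevelEmphasis": float((mat * i ** 2).sum() / nd),
        "LargeDependenceEmphasis": float((mat * j ** 2).sum() / nd),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (mat * i ** 2 * j ** 2).sum() / nd),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (mat * j ** 2 / i ** 2).sum() / nd),
        "LowGrayLevelEmphasis": float((mat / i ** 2).sum() / nd),
        "SmallDependenceEmphasis": float((mat / j ** 2).sum() / nd),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (mat * i ** 2 / j ** 2).sum() / nd),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (mat / (i ** 2 * j ** 2)).sum() / nd),
    }


NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def ngtdm_features(n_i: np.ndarray, p_i: np.ndarray, s_i: np.ndarray
                   ) -> dict[str, float]:
    """5 neighbourhood gray-tone difference features.

    A region with a single occupied level (or no valid voxels) yields 0 for
    Contrast, Strength, Busyness and Complexity; Coarseness saturates at the
    reciprocal of the machine tiny when the weighted sum vanishes.
    """
    nv = n_i.sum()
    present = p_i > 0
    ngp = int(present.sum())
    if nv == 0 or ngp == 0:
        return {name: 0.0 for name in NGTDM_NAMES}
    i = np.arange(1, len(p_i) + 1, dtype=np.float64)
    ip = i[present]
    pp = p_i[present]
    sp = s_i[present]
    sum_s = s_i.sum()
    coarse = float(1.0 / max((pp * sp).sum(), _EPS))
    if ngp == 1:
        return {"Busyness": 0.0, "Coarseness": coarse, "Complexity": 0.0,
                "Contrast": 0.0, "Strength": 0.0}
    di = ip[:, None] - ip[None, :]
    pij = pp[:, None] * pp[None, :]
    contrast = float((pij * di ** 2).sum() / (ngp * (ngp - 1)) * (sum_s / nv))
    busy_den = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
    busyness = float((pp * sp).sum() / busy_den) if busy_den > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        comp = (np.abs(di) * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :]))
    complexity = float(comp.sum() / nv)
    strength = float(((pp[:, None] + pp[None, :]) * di ** 2).sum() / sum_s) \
        if sum_s > 0 else 0.0
    return {"Busyness": busyness, "Coarseness": coarse,
            "Complexity": complexity, "Contrast": contrast,
            "Strength": strength}


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

SHAPE_NAMES = (
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice", "Maximum3DDiameter", "MeshVolume",
    "MinorAxisLength", "Sphericity", "SurfaceArea", "SurfaceVolumeRatio",
    "VoxelVolume",
)


def shape_features(region: np.ndarray, spacing_mm) -> dict[str, float]:
    """14 shape descriptors of a boolean 3-D region.

    Surface area and mesh volume come from a marching-cubes mesh of the
    0.5-isosurface; axis lengths from PCA of physical voxel-centre
    coordinates (length = 4 * sqrt(eigenvalue), the ellipsoid convention).
    The three Maximum2DDiameter features fix, in turn, axis 1 (Column),
    axis 0 (Row) and axis 2 (Slice) and take the largest in-plane boundary
    voxel separation.
    """
    from skimage import measure

    region = np.asarray(region, dtype=bool)
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    n = int(region.sum())
    if n == 0:
        raise ValueError("shape features of an empty region")
    voxel_volume = float(np.prod(spacing))

    padded = np.pad(region.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum(
        "ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0))

    coords = np.argwhere(region).astype(np.float64) * spacing
    centered = coords - coords.mean(axis=0)
    if n > 1:
        cov = centered.T @ centered / n
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    border = region & ~ndimage.binary_erosion(region)
    bcoords = np.argwhere(border).astype(np.float64) * spacing

    def _max_pairwise(pts):
        if len(pts) < 2:
            return 0.0
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.max()))

    def _max_planar(fixed_axis):
        best = 0.0
        keep = [ax for ax in range(3) if ax != fixed_axis]
        vals = np.unique(bcoords[:, fixed_axis])
        for v in vals:
            pts = bcoords[bcoords[:, fixed_axis] == v][:, keep]
            best = max(best, _max_pairwise(pts))
        return best

    sphericity = float((36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0)
                       / surface_area) if surface_area > 0 else 0.0
    return {
        "Elongation": elongation,
        "Flatness": flatness,
        "LeastAxisLength": least,
        "MajorAxisLength": major,
        "Maximum2DDiameterColumn": _max_planar(1),
        "Maximum2DDiameterRow": _max_planar(0),
        "Maximum2DDiameterSlice": _max_planar(2),
        "Maximum3DDiameter": _max_pairwise(bcoords),
        "MeshVolume": mesh_volume,
        "MinorAxisLength": minor,
        "Sphericity": sphericity,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": float(surface_area / mesh_volume)
        if mesh_volume > 0 else 0.0,
        "VoxelVolume": float(n * voxel_volume),
    }
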