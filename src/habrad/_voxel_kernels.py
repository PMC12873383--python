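"""JIT-compiled per-voxel texture kernels.

Each kernel sweeps every foreground voxel, gathers the cubic neighbourhood
clipped to the VOI, discretizes it over its local min-max, and evaluates one
feature family.  Conventions mirror :mod:`habrad.texture` (symmetric GLCM
pooled over the 13 unique directions, run/zone matrices pooled likewise,
entropies in bits); degenerate neighbourhoods take the constant-image limits
(JointEnergy 1, every other co-occurrence feature 0).
"""

from __future__ import annotations

import numpy as np
from numba import njit

OFFSETS_13 = np.array([
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
], dtype=np.int64)


@njit(cache=True)
def _gather(vals, fg, x, y, z, radius, nbv, lev, raw):
    """Fill the local level cube ``lev`` (0 outside VOI) and raw values.

    Returns the number of in-VOI neighbourhood voxels.  ``lev`` holds the
    discretized level for gathered voxels; ``raw`` the raw intensity on the
    same local grid; ``nbv`` the flat list of raw values.
    """
    nx, ny, nz = vals.shape
    box = 2 * radius + 1
    cnt = 0
    for a in range(box):
        for b in range(box):
            for c in range(box):
                lev[a, b, c] = 0
                raw[a, b, c] = 0.0
    lo = np.inf
    hi = -np.inf
    for dx in range(-radius, radius + 1):
        xx = x + dx
        if xx < 0 or xx >= nx:
            continue
        for dy in range(-radius, radius + 1):
            yy = y + dy
            if yy < 0 or yy >= ny:
                continue
            for dz in range(-radius, radius + 1):
                zz = z + dz
                if zz < 0 or zz >= nz:
                    continue
                if not fg[xx, yy, zz]:
                    continue
                v = vals[xx, yy, zz]
                nbv[cnt] = v
                cnt += 1
                raw[dx + radius, dy + radius, dz + radius] = v
                lev[dx + radius, dy + radius, dz + radius] = -1  # mark inside
                if v < lo:
                    lo = v
                if v > hi:
                    hi = v
    return cnt, lo, hi


@njit(cache=True)
def _discretize_cube(lev, raw, lo, hi, n_levels, radius):
    box = 2 * radius + 1
    if hi == lo:
        for a in range(box):
            for b in range(box):
                for c in range(box):
                    if lev[a, b, c] == -1:
                        lev[a, b, c] = 1
        return
    width = (hi - lo) / n_levels
    for a in range(box):
        for b in range(box):
            for c in range(box):
                if lev[a, b, c] == -1:
                    g = int((raw[a, b, c] - lo) / width) + 1
                    if g > n_levels:
                        g = n_levels
                    if g < 1:
                        g = 1
                    lev[a, b, c] = g


@njit(cache=True)
def first_order_maps(vals, fg, radius, n_levels):
    """Maps 0..2: Entropy (bits, discretized), MeanAbsoluteDeviation, Median."""
    nx, ny, nz = vals.shape
    out = np.full((3, nx, ny, nz), np.nan)
    box = 2 * radius + 1
    nbv = np.empty(box ** 3)
    lev = np.zeros((box, box, box), dtype=np.int64)
    raw = np.zeros((box, box, box))
    hist = np.zeros(n_levels)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not fg[x, y, z]:
                    continue
                cnt, lo, hi = _gather(vals, fg, x, y, z, radius, nbv, lev, raw)
                _discretize_cube(lev, raw, lo, hi, n_levels, radius)
                for i in range(n_levels):
                    hist[i] = 0.0
                for a in range(box):
                    for b in range(box):
                        for c in range(box):
                            if lev[a, b, c] > 0:
                                hist[lev[a, b, c] - 1] += 1.0
                ent = 0.0
                for i in range(n_levels):
                    if hist[i] > 0:
                        p = hist[i] / cnt
                        ent -= p * np.log2(p)
                mean = 0.0
                for i in range(cnt):
                    mean += nbv[i]
                mean /= cnt
                mad = 0.0
                for i in range(cnt):
                    mad += abs(nbv[i] - mean)
                mad /= cnt
                sorted_v = np.sort(nbv[:cnt])
                if cnt % 2 == 1:
                    med = sorted_v[cnt // 2]
                else:
                    med = 0.5 * (sorted_v[cnt // 2 - 1] + sorted_v[cnt // 2])
                out[0, x, y, z] = ent
                out[1, x, y, z] = mad
                out[2, x, y, z] = med
    return out


@njit(cache=True)
def _glcm_features_from_mat(mat, n_levels):
    """9 Table-4 GLCM features from an (unnormalised) symmetric matrix."""
    total = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            total += mat[i, j]
    feats = np.zeros(9)
    if total == 0.0:
        feats[5] = 1.0  # JointEnergy constant-image limit
        return feats
    p_diff = np.zeros(n_levels)
    p_sum = np.zeros(2 * n_levels - 1)
    px = np.zeros(n_levels)
    energy = 0.0
    hxy = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            p = mat[i, j] / total
            if p > 0:
                hxy -= p * np.log2(p)
            energy += p * p
            p_diff[abs(i - j)] += p
            p_sum[i + j] += p
            px[i] += p
    da = 0.0
    for k in range(n_levels):
        da += k * p_diff[k]
    de = 0.0
    dv = 0.0
    iv = 0.0
    for k in range(n_levels):
        if p_diff[k] > 0:
            de -= p_diff[k] * np.log2(p_diff[k])
        dv += (k - da) ** 2 * p_diff[k]
        if k >= 1:
            iv += p_diff[k] / (k * k)
    se = 0.0
    for k in range(2 * n_levels - 1):
        if p_sum[k] > 0:
            se -= p_sum[k] * np.log2(p_sum[k])
    hx = 0.0
    for i in range(n_levels):
        if px[i] > 0:
            hx -= px[i] * np.log2(px[i])
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            q = px[i] * px[j]
            if q > 0:
                hxy2 -= q * np.log2(q)
                p = mat[i, j] / total
                if p > 0:
                    hxy1 -= p * np.log2(q)
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = np.sqrt(arg) if arg > 0 else 0.0
    feats[0] = da
    feats[1] = de
    feats[2] = dv
    feats[3] = imc1
    feats[4] = imc2
    feats[5] = energy
    feats[6] = hxy
    feats[7] = se
    feats[8] = iv
    return feats


@njit(cache=True)
def glcm_maps(vals, fg, radius, n_levels, distance):
    """Maps: DifferenceAverage, DifferenceEntropy, DifferenceVariance,
    Imc1, Imc2, JointEnergy(index 5), JointEntropy, SumEntropy,
    InverseVariance(index 8)."""
    nx, ny, nz = vals.shape
    out = np.full((9, nx, ny, nz), np.nan)
    box = 2 * radius + 1
    nbv = np.empty(box ** 3)
    lev = np.zeros((box, box, box), dtype=np.int64)
    raw = np.zeros((box, box, box))
    mat = np.zeros((n_levels, n_levels))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not fg[x, y, z]:
                    continue
                cnt, lo, hi = _gather(vals, fg, x, y, z, radius, nbv, lev, raw)
                _discretize_cube(lev, raw, lo, hi, n_levels, radius)
                for i in range(n_levels):
                    for j in range(n_levels):
                        mat[i, j] = 0.0
                for t in range(13):
                    ox = OFFSETS_13[t, 0] * distance
                    oy = OFFSETS_13[t, 1] * distance
                    oz = OFFSETS_13[t, 2] * distance
                    for a in range(box):
                        aa = a + ox
                        if aa < 0 or aa >= box:
                            continue
                        for b in range(box):
                            bb = b + oy
                            if bb < 0 or bb >= box:
                                continue
                            for c in range(box):
                                cc = c + oz
                                if cc < 0 or cc >= box:
                                    continue
                                gi = lev[a, b, c]
                                gj = lev[aa, bb, cc]
                                if gi > 0 and gj > 0:
                                    mat[gi - 1, gj - 1] += 1.0
                                    mat[gj - 1, gi - 1] += 1.0
                feats = _glcm_features_from_mat(mat, n_levels)
                for f in range(9):
                    out[f, x, y, z] = feats[f]
    return out


@njit(cache=True)
def glrlm_maps(vals, fg, radius, n_levels):
    """Maps: LongRunEmphasis, RunEntropy, RunVariance (13-direction pooled)."""
    nx, ny, nz = vals.shape
    out = np.full((3, nx, ny, nz), np.nan)
    box = 2 * radius + 1
    nbv = np.empty(box ** 3)
    lev = np.zeros((box, box, box), dtype=np.int64)
    raw = np.zeros((box, box, box))
    runmat = np.zeros((n_levels, box))
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not fg[x, y, z]:
                    continue
                cnt, lo, hi = _gather(vals, fg, x, y, z, radius, nbv, lev, raw)
                _discretize_cube(lev, raw, lo, hi, n_levels, radius)
                for i in range(n_levels):
                    for j in range(box):
                        runmat[i, j] = 0.0
                for t in range(13):
                    ox = OFFSETS_13[t, 0]
                    oy = OFFSETS_13[t, 1]
                    oz = OFFSETS_13[t, 2]
                    for a in range(box):
                        for b in range(box):
                            for c in range(box):
                                g = lev[a, b, c]
                                if g <= 0:
                                    continue
                                pa = a - ox
                                pb = b - oy
                                pc = c - oz
                                if (0 <= pa < box and 0 <= pb < box
                                        and 0 <= pc < box
                                        and lev[pa, pb, pc] == g):
                                    continue  # not a run start
                                length = 1
                                na, nb_, nc = a + ox, b + oy, c + oz
                                while (0 <= na < box and 0 <= nb_ < box
                                       and 0 <= nc < box
                                       and lev[na, nb_, nc] == g):
                                    length += 1
                                    na += ox
                                    nb_ += oy
                                    nc += oz
                                runmat[g - 1, length - 1] += 1.0
                nr = 0.0
                for i in range(n_levels):
                    for j in range(box):
                        nr += runmat[i, j]
                lre = 0.0
                rent = 0.0
                mu_l = 0.0
                for i in range(n_levels):
                    for j in range(box):
                        if runmat[i, j] > 0:
                            p = runmat[i, j] / nr
                            lre += p * (j + 1) ** 2
                            rent -= p * np.log2(p)
                            mu_l += p * (j + 1)
                rvar = 0.0
                for i in range(n_levels):
                    for j in range(box):
                        if runmat[i, j] > 0:
                            rvar += (runmat[i, j] / nr) * ((j + 1) - mu_l) ** 2
                out[0, x, y, z] = lre
                out[1, x, y, z] = rent
                out[2, x, y, z] = rvar
    return out


@njit(cache=True)
def glszm_maps(vals, fg, radius, n_levels):
    """Maps: SizeZoneNonUniformityNormalized, SmallAreaHighGrayLevelEmphasis."""
    nx, ny, nz = vals.shape
    out = np.full((2, nx, ny, nz), np.nan)
    box = 2 * radius + 1
    maxn = box ** 3
    nbv = np.empty(maxn)
    lev = np.zeros((box, box, box), dtype=np.int64)
    raw = np.zeros((box, box, box))
    visited = np.zeros((box, box, box), dtype=np.int64)
    stack = np.empty((maxn, 3), dtype=np.int64)
    zone_level = np.empty(maxn, dtype=np.int64)
    zone_size = np.empty(maxn, dtype=np.int64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not fg[x, y, z]:
                    continue
                cnt, lo, hi = _gather(vals, fg, x, y, z, radius, nbv, lev, raw)
                _discretize_cube(lev, raw, lo, hi, n_levels, radius)
                for a in range(box):
                    for b in range(box):
                        for c in range(box):
                            visited[a, b, c] = 0
                n_zones = 0
                for a in range(box):
                    for b in range(box):
                        for c in range(box):
                            g = lev[a, b, c]
                            if g <= 0 or visited[a, b, c]:
                                continue
                            # 26-connected flood fill
                            size = 0
                            top = 0
                            stack[top, 0] = a
                            stack[top, 1] = b
                            stack[top, 2] = c
                            top += 1
                            visited[a, b, c] = 1
                            while top > 0:
                                top -= 1
                                ca = stack[top, 0]
                                cb = stack[top, 1]
                                cc = stack[top, 2]
                                size += 1
                                for da in range(-1, 2):
                                    na = ca + da
                                    if na < 0 or na >= box:
                                        continue
                                    for db in range(-1, 2):
                                        nb_ = cb + db
                                        if nb_ < 0 or nb_ >= box:
                                            continue
                                        for dc in range(-1, 2):
                                            ncc = cc + dc
                                            if ncc < 0 or ncc >= box:
                                                continue
                                            if (visited[na, nb_, ncc] == 0
                                                    and lev[na, nb_, ncc] == g):
                                                visited[na, nb_, ncc] = 1
                                                stack[top, 0] = na
                                                stack[top, 1] = nb_
                                                stack[top, 2] = ncc
                                                top += 1
                            zone_level[n_zones] = g
                            zone_size[n_zones] = size
                            n_zones += 1
                # features
                nz_tot = float(n_zones)
                # zone-size histogram for SZNN
                sznn = 0.0
                for s in range(1, cnt + 1):
                    cs = 0.0
                    for q in range(n_zones):
                        if zone_size[q] == s:
                            cs += 1.0
                    sznn += cs * cs
                sznn /= nz_tot * nz_tot
                sahgle = 0.0
                for q in range(n_zones):
                    sahgle += (zone_level[q] ** 2) / float(zone_size[q] ** 2)
                sahgle /= nz_tot
                out[0, x, y, z] = sznn
                out[1, x, y, z] = sahgle
    return out


@njit(cache=True)
def ngtdm_maps(vals, fg, radius, n_levels):
    """Maps: Contrast, Strength (26-neighbour gray-tone differences)."""
    nx, ny, nz = vals.shape
    out = np.full((2, nx, ny, nz), np.nan)
    box = 2 * radius + 1
    nbv = np.empty(box ** 3)
    lev = np.zeros((box, box, box), dtype=np.int64)
    raw = np.zeros((box, box, box))
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not fg[x, y, z]:
                    continue
                cnt, lo, hi = _gather(vals, fg, x, y, z, radius, nbv, lev, raw)
                _discretize_cube(lev, raw, lo, hi, n_levels, radius)
                for i in range(n_levels):
                    n_i[i] = 0.0
                    s_i[i] = 0.0
                for a in range(box):
                    for b in range(box):
                        for c in range(box):
                            g = lev[a, b, c]
                            if g <= 0:
                                continue
                            nsum = 0.0
                            ncnt = 0
                            for da in range(-1, 2):
                                na = a + da
                                if na < 0 or na >= box:
                                    continue
                                for db in range(-1, 2):
                                    nb_ = b + db
                                    if nb_ < 0 or nb_ >= box:
                                        continue
                                    for dc in range(-1, 2):
                                        ncc = c + dc
                                        if ncc < 0 or ncc >= box:
                                            continue
                                        if da == 0 and db == 0 and dc == 0:
                                            continue
                                        gg = lev[na, nb_, ncc]
                                        if gg > 0:
                                            nsum += gg
                                            ncnt += 1
                            if ncnt > 0:
                                n_i[g - 1] += 1.0
                                s_i[g - 1] += abs(g - nsum / ncnt)
                nv = 0.0
                ngp = 0
                sum_s = 0.0
                for i in range(n_levels):
                    nv += n_i[i]
                    sum_s += s_i[i]
                    if n_i[i] > 0:
                        ngp += 1
                contrast = 0.0
                strength = 0.0
                if nv > 0 and ngp > 1:
                    acc = 0.0
                    sacc = 0.0
                    for i in range(n_levels):
                        if n_i[i] == 0:
                            continue
                        pi = n_i[i] / nv
                        for j in range(n_levels):
                            if n_i[j] == 0:
                                continue
                            pj = n_i[j] / nv
                            acc += pi * pj * (i - j) ** 2
                            sacc += (pi + pj) * (i - j) ** 2
                    contrast = acc / (ngp * (ngp - 1)) * (sum_s / nv)
                    strength = sacc / sum_s if sum_s > 0 else 0.0
                out[0, x, y, z] = contrast
                out[1, x, y, z] = strength
    return out
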