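"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops and elementary formulas,
deliberately sharing no code path with the package, so that agreement between
the two is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


# ---------------------------------------------------------------------------
# GLCM

def glcm_oracle(levels, mask, direction, distance, n_levels):
    """Symmetric normalized co-occurrence matrix by explicit pixel loops."""
    dr, dc = _OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((n_levels, n_levels))
    R, C = mask.shape
    n_pairs = 0
    for r in range(R):
        for c in range(C):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < R and 0 <= c2 < C and mask[r, c] and mask[r2, c2]:
                a, b = levels[r, c] - 1, levels[r2, c2] - 1
                counts[a, b] += 1
                counts[b, a] += 1
                n_pairs += 1
    if n_pairs == 0:
        return None
    return counts / counts.sum()


def glcm_features_oracle(p):
    """The 11 co-occurrence features from first principles (log2 entropies)."""
    Ng = p.shape[0]
    px = [sum(p[i][j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(p[i][j] for i in range(Ng)) for j in range(Ng)]
    mu_x = sum((i + 1) * px[i] for i in range(Ng))
    mu_y = sum((j + 1) * py[j] for j in range(Ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(Ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(Ng))

    asm = contrast = idm = e_ij = entropy = 0.0
    for i in range(Ng):
        for j in range(Ng):
            v = p[i][j]
            asm += v * v
            contrast += (i - j) ** 2 * v
            idm += v / (1.0 + (i - j) ** 2)
            e_ij += (i + 1) * (j + 1) * v
            if v > 0:
                entropy -= v * math.log2(v)
    if var_x > 0 and var_y > 0:
        correlat = (e_ij - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        correlat = 0.0

    p_sum = {}
    p_diff = {}
    for i in range(Ng):
        for j in range(Ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i][j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i][j]
    sum_averg = sum(k * v for k, v in p_sum.items())
    sum_varnc = sum((k - sum_averg) ** 2 * v for k, v in p_sum.items())
    sum_entrp = -sum(v * math.log2(v) for v in p_sum.values() if v > 0)
    mu_d = sum(k * v for k, v in p_diff.items())
    dif_varnc = sum((k - mu_d) ** 2 * v for k, v in p_diff.items())
    dif_entrp = -sum(v * math.log2(v) for v in p_diff.values() if v > 0)

    return {"AngScMom": asm, "Contrast": contrast, "Correlat": correlat,
            "SumOfSqs": var_x, "InvDfMom": idm, "SumAverg": sum_averg,
            "SumVarnc": sum_varnc, "SumEntrp": sum_entrp, "Entropy": entropy,
            "DifVarnc": dif_varnc, "DifEntrp": dif_entrp}


# ---------------------------------------------------------------------------
# GLRLM

def _lines_oracle(shape, direction):
    """Pixel coordinate lists of every collinear line along a direction."""
    R, C = shape
    lines = []
    if direction == 0:
        for r in range(R):
            lines.append([(r, c) for c in range(C)])
    elif direction == 90:
        for c in range(C):
            lines.append([(r, c) for r in range(R)])
    elif direction == 45:    # successive pixels step (+1, +1)
        for d in range(-(R - 1), C):
            lines.append([(r, r + d) for r in range(R) if 0 <= r + d < C])
    elif direction == 135:   # successive pixels step (+1, -1)
        for s in range(R + C - 1):
            lines.append([(r, s - r) for r in range(R) if 0 <= s - r < C])
    else:
        raise ValueError(direction)
    return [ln for ln in lines if ln]


def glrlm_oracle(levels, mask, direction):
    """Sorted multiset of (level, run length) runs found by explicit scanning."""
    runs = []
    for line in _lines_oracle(mask.shape, direction):
        cur_level, cur_len = None, 0
        for (r, c) in line + [(-1, -1)]:
            lv = levels[r, c] if r >= 0 and mask[r, c] else None
            if lv == cur_level and lv is not None:
                cur_len += 1
            else:
                if cur_level is not None:
                    runs.append((int(cur_level), cur_len))
                cur_level, cur_len = lv, 1
    return sorted(runs)


def glrlm_features_oracle(runs, n_pixels):
    nr = len(runs)
    sre = sum(1.0 / l ** 2 for _, l in runs) / nr
    lre = sum(float(l) ** 2 for _, l in runs) / nr
    by_level = {}
    by_length = {}
    for g, l in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    gln = sum(v ** 2 for v in by_level.values()) / nr
    rln = sum(v ** 2 for v in by_length.values()) / nr
    return {"ShrtREmp": sre, "LngREmph": lre, "GLevNonUni": gln,
            "RLNonUni": rln, "Fraction": nr / n_pixels}


# ---------------------------------------------------------------------------
# histogram / gradient

def histogram_oracle(values):
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    if var == 0:
        skew = kurt = 0.0
    else:
        sd = math.sqrt(var)
        skew = sum(((v - mean) / sd) ** 3 for v in x) / n
        kurt = sum(((v - mean) / sd) ** 4 for v in x) / n - 3.0
    s = sorted(x)
    out = {"Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt}
    for pct in (1, 10, 25, 50, 75, 90, 99):
        idx = max(1, math.ceil(pct / 100.0 * n)) - 1
        out[f"Perc_{pct:02d}"] = s[idx]
    return out


def gradient_oracle(levels, mask):
    """Half central differences over pixels whose four neighbors are in-mask."""
    R, C = mask.shape
    mags = []
    for r in range(1, R - 1):
        for c in range(1, C - 1):
            if (mask[r, c] and mask[r - 1, c] and mask[r + 1, c]
                    and mask[r, c - 1] and mask[r, c + 1]):
                dy = (float(levels[r + 1, c]) - float(levels[r - 1, c])) / 2.0
                dx = (float(levels[r, c + 1]) - float(levels[r, c - 1])) / 2.0
                mags.append(math.hypot(dx, dy))
    if not mags:
        return None
    n = len(mags)
    mean = sum(mags) / n
    var = sum((v - mean) ** 2 for v in mags) / n
    if var == 0:
        skew = kurt = 0.0
    else:
        sd = math.sqrt(var)
        skew = sum(((v - mean) / sd) ** 3 for v in mags) / n
        kurt = sum(((v - mean) / sd) ** 4 for v in mags) / n - 3.0
    nz = sum(1 for v in mags if v > 0) / n
    return {"GrMean": mean, "GrVariance": var, "GrSkewness": skew,
            "GrKurtosis": kurt, "GrNonZeros": nz}


# ---------------------------------------------------------------------------
# Haar wavelet (even-sized arrays: non-overlapping pairwise filters)

def _haar_pairs(a, axis):
    a = np.moveaxis(np.asarray(a, float), axis, 0)
    lo = (a[0::2] + a[1::2]) / math.sqrt(2.0)
    hi = (a[0::2] - a[1::2]) / math.sqrt(2.0)
    return np.moveaxis(lo, 0, axis), np.moveaxis(hi, 0, axis)


def haar_energies_oracle(patch, n_scales):
    """Per-scale subband mean square energies for an even-sized patch.

    Subband naming: first letter is the filter along rows (axis 0).  Returns
    a dict keyed like ``WavEnHL_s1``; stops once a dimension turns odd or
    reaches 1 (matching availability, not padding behavior).
    """
    out = {}
    cur = np.asarray(patch, float)
    for s in range(1, n_scales + 1):
        if min(cur.shape) < 2 or cur.shape[0] % 2 or cur.shape[1] % 2:
            break
        lo_r, hi_r = _haar_pairs(cur, 0)
        ll, lh = _haar_pairs(lo_r, 1)
        hl, hh = _haar_pairs(hi_r, 1)
        for band, coef in (("WavEnLL", ll), ("WavEnLH", lh),
                           ("WavEnHL", hl), ("WavEnHH", hh)):
            out[f"{band}_s{s}"] = float(np.mean(np.square(np.abs(coef))))
        cur = ll
    return out


# ---------------------------------------------------------------------------
# AUC / Wilcoxon / ICC / Spearman

def auc_oracle(scores, labels):
    """All-pairs concordance with ties counted one half."""
    pos = [float(s) for s, y in zip(scores, labels) if y == 1]
    neg = [float(s) for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def _u_statistic(x, y):
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def wilcoxon_exact_oracle(x, y):
    """Exact two-sided rank-sum p-value by full enumeration (tie-free data)."""
    combined = list(x) + list(y)
    n1 = len(x)
    center = n1 * len(y) / 2.0
    u_obs = _u_statistic(x, y)
    count = total = 0
    idx = range(len(combined))
    for chosen in combinations(idx, n1):
        grp1 = [combined[i] for i in chosen]
        grp2 = [combined[i] for i in idx if i not in chosen]
        u = _u_statistic(grp1, grp2)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


def icc_oracle(ratings, model="icc2"):
    """Two-way ANOVA ICC by explicit sums of squares."""
    m = [[float(v) for v in row] for row in ratings]
    n = len(m)
    k = len(m[0])
    grand = sum(sum(row) for row in m) / (n * k)
    row_means = [sum(row) / k for row in m]
    col_means = [sum(m[i][j] for i in range(n)) / n for j in range(k)]
    sst = sum((m[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    if sst == 0:
        return 1.0
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if model == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    return 1.0 if denom == 0 else (msr - mse) / denom


def _ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho: Pearson correlation of average ranks."""
    rx, ry = _ranks(list(x)), _ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


# ---------------------------------------------------------------------------
# random small test instances

def random_discrete_instance(rng, max_side=12, max_levels=8):
    """A random small level image with a random (non-empty) blob-ish mask."""
    R = int(rng.integers(3, max_side + 1))
    C = int(rng.integers(3, max_side + 1))
    Ng = int(rng.integers(2, max_levels + 1))
    levels = rng.integers(1, Ng + 1, size=(R, C))
    mask = rng.random((R, C)) < rng.uniform(0.4, 1.0)
    if not mask.any():
        mask[R // 2, C // 2] = True
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int32), mask, Ng
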