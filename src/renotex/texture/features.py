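"""The six texture-feature families computed on a discretized ROI.

Families: gray-level histogram, absolute gradient, causal autoregressive
model, gray-level co-occurrence matrix (GLCM, the standard 11-feature
Haralick subset, log2 entropies), gray-level run-length matrix (GLRLM) and
Haar wavelet subband energies.  All features operate on integer levels
``1..Ng`` produced by :func:`renotex.imaging.normalize_gray_levels`.

Direction convention (row axis points down, image coordinates): 0 deg is the
+column offset ``(0, d)``, 90 deg the +row offset ``(d, 0)``, 45 deg the main
diagonal ``(d, d)`` and 135 deg the anti-diagonal ``(d, -d)``.  GLCMs are
accumulated symmetrically and normalized to sum 1.

Sentinel policy: a registry cell that cannot be computed (no pixel pair at a
displacement, wavelet scale deeper than the patch allows) contributes value 0
with its validity flag cleared, so the vector length is stable for modeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import pywt

from ..imaging import DiscretizedImage, normalize_gray_levels
from .registry import (
    AR_NAMES,
    DIRECTIONS,
    DISTANCES,
    GLCM_NAMES,
    GLRLM_NAMES,
    GRAD_NAMES,
    HIST_NAMES,
    WAVELET_SCALES,
    WAVELET_SUBBANDS,
    FeatureRegistry,
    default_registry,
)

__all__ = [
    "FeatureVector",
    "GLCMatrix",
    "GLRLMatrix",
    "NoPixelPairsError",
    "histogram_features",
    "gradient_features",
    "ar_features",
    "glcm_compute",
    "glcm_features",
    "glcm_direction_average",
    "glrlm_compute",
    "glrlm_features",
    "wavelet_features",
    "extract_all",
    "feature_table",
]


class NoPixelPairsError(ValueError):
    """No valid in-mask pixel pair exists at the requested displacement."""


# ---------------------------------------------------------------------------
# shared helpers

def _moments(x: np.ndarray) -> Tuple[float, float, float, float]:
    """Population mean, variance, skewness (mu3/sigma^3) and excess kurtosis.

    Skewness and kurtosis are 0 by convention for a degenerate (constant)
    sample.
    """
    mean = float(x.mean())
    var = float(x.var())
    if var == 0:
        return mean, 0.0, 0.0, 0.0
    z = (x - mean) / math.sqrt(var)
    return mean, var, float((z ** 3).mean()), float((z ** 4).mean() - 3.0)


def _nearest_rank(sorted_x: np.ndarray, pct: float) -> float:
    n = sorted_x.size
    idx = max(1, math.ceil(pct / 100.0 * n)) - 1
    return float(sorted_x[idx])


# ---------------------------------------------------------------------------
# histogram

def histogram_features(d: DiscretizedImage) -> Dict[str, float]:
    """First-order statistics of the in-mask gray levels."""
    x = d.in_mask_levels.astype(float)
    if x.size == 0:
        raise ValueError("empty mask")
    mean, var, skew, kurt = _moments(x)
    s = np.sort(x)
    out = {"Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt}
    for pct in (1, 10, 25, 50, 75, 90, 99):
        out[f"Perc_{pct:02d}"] = _nearest_rank(s, pct)
    return out


# ---------------------------------------------------------------------------
# gradient

def gradient_features(d: DiscretizedImage) -> Dict[str, float]:
    """Moments of the absolute gradient magnitude over interior pixels.

    Central differences are evaluated only where all four 4-neighbors are
    in-mask; the magnitude is sqrt(dx^2 + dy^2) with dx, dy the half
    differences along columns and rows.
    """
    m = d.mask
    interior = (m
                & np.roll(m, 1, 0) & np.roll(m, -1, 0)
                & np.roll(m, 1, 1) & np.roll(m, -1, 1))
    # roll wraps; forbid border pixels outright
    interior[0, :] = interior[-1, :] = False
    interior[:, 0] = interior[:, -1] = False
    if not interior.any():
        raise ValueError("mask has no interior pixels for the gradient")
    lv = d.levels.astype(float)
    dy = (np.roll(lv, -1, 0) - np.roll(lv, 1, 0)) / 2.0
    dx = (np.roll(lv, -1, 1) - np.roll(lv, 1, 1)) / 2.0
    mag = np.hypot(dx, dy)[interior]
    mean, var, skew, kurt = _moments(mag)
    return {"GrMean": mean, "GrVariance": var, "GrSkewness": skew,
            "GrKurtosis": kurt, "GrNonZeros": float((mag > 0).mean())}


# ---------------------------------------------------------------------------
# autoregressive model

_CAUSAL_OFFSETS = ((-1, 0), (0, -1), (-1, -1), (-1, 1))


def ar_features(d: DiscretizedImage, min_pixels: int = 20,
                ridge: float = 1e-8) -> Dict[str, float]:
    """Causal 2D autoregressive coefficients Teta1..Teta4 and residual SD.

    The level at (i, j) is regressed on its four causal neighbors
    (i-1,j), (i,j-1), (i-1,j-1), (i-1,j+1) by least squares with the response
    and each regressor centered on its own mean (equivalent to fitting an
    intercept).  A rank-deficient design falls back to a tiny-ridge solve.
    """
    m = d.mask
    lv = d.levels.astype(float)
    valid = m.copy()
    valid[0, :] = False
    valid[:, 0] = False
    valid[:, -1] = False
    for dr, dc in _CAUSAL_OFFSETS:
        shifted = np.roll(np.roll(m, -dr, 0), -dc, 1)
        valid &= shifted
    if valid.sum() < min_pixels:
        raise ValueError(
            f"need >= {min_pixels} pixels with full causal neighborhoods")
    rr, cc = np.nonzero(valid)
    y = lv[rr, cc]
    X = np.column_stack([lv[rr + dr, cc + dc] for dr, dc in _CAUSAL_OFFSETS])
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    rank = np.linalg.matrix_rank(Xc)
    if rank < 4:
        G = Xc.T @ Xc + ridge * np.eye(4)
        theta = np.linalg.solve(G, Xc.T @ yc)
    else:
        theta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ theta
    return {"Teta1": float(theta[0]), "Teta2": float(theta[1]),
            "Teta3": float(theta[2]), "Teta4": float(theta[3]),
            "Sigma": float(resid.std())}


# ---------------------------------------------------------------------------
# co-occurrence matrix

@dataclass
class GLCMatrix:
    """Symmetric, normalized co-occurrence probabilities for one offset."""

    p: np.ndarray
    direction: int
    distance: int
    n_pairs: int


_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def _offset_pairs(d: DiscretizedImage, dr: int, dc: int
                  ) -> Tuple[np.ndarray, np.ndarray]:
    m = d.mask
    R, C = m.shape
    r0 = slice(max(0, -dr), min(R, R - dr))
    c0 = slice(max(0, -dc), min(C, C - dc))
    r1 = slice(max(0, dr), min(R, R + dr))
    c1 = slice(max(0, dc), min(C, C + dc))
    both = m[r0, c0] & m[r1, c1]
    return d.levels[r0, c0][both], d.levels[r1, c1][both]


def glcm_compute(d: DiscretizedImage, direction: int,
                 distance: int) -> GLCMatrix:
    """Accumulate the symmetric GLCM at one (direction, distance)."""
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {sorted(_OFFSETS)}")
    dr, dc = _OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    a, b = _offset_pairs(d, dr, dc)
    if a.size == 0:
        raise NoPixelPairsError(
            f"no in-mask pixel pair at direction {direction}, "
            f"distance {distance}")
    Ng = d.n_bins
    counts = np.bincount((a.astype(np.int64) - 1) * Ng + (b - 1),
                         minlength=Ng * Ng).reshape(Ng, Ng).astype(float)
    counts += counts.T
    return GLCMatrix(p=counts / counts.sum(), direction=direction,
                     distance=distance, n_pairs=int(a.size))


@lru_cache(maxsize=8)
def _glcm_grids(Ng: int):
    i = np.arange(1, Ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff2 = (ii - jj) ** 2
    inv_diff = 1.0 / (1.0 + diff2)
    sum_idx = (ii + jj).astype(np.int64).ravel()          # 2..2Ng
    absdiff_idx = np.abs(ii - jj).astype(np.int64).ravel()  # 0..Ng-1
    return i, diff2, inv_diff, sum_idx, absdiff_idx


def glcm_features(m: GLCMatrix) -> Dict[str, float]:
    """The 11 Haralick-type features of one normalized GLCM (log2 entropies)."""
    p = m.p
    total = p.sum()
    if abs(total - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum 1")
    Ng = p.shape[0]
    i, diff2, inv_diff, sum_idx, absdiff_idx = _glcm_grids(Ng)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    asm = float((p * p).sum())
    contrast = float((diff2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlat = (float(i @ p @ i) - mu_x * mu_y) / math.sqrt(var_x * var_y)
    else:
        correlat = 0.0
    sum_of_sqs = float(((i - mu_x) ** 2) @ px)
    inv_df_mom = float((inv_diff * p).sum())

    flat = p.ravel()
    p_sum = np.bincount(sum_idx, weights=flat, minlength=2 * Ng + 1)
    k_sum = np.arange(p_sum.size, dtype=float)
    sum_averg = float(k_sum @ p_sum)
    sum_varnc = float(((k_sum - sum_averg) ** 2) @ p_sum)
    nz = p_sum > 0
    sum_entrp = float(-(p_sum[nz] * np.log2(p_sum[nz])).sum())

    nzp = flat > 0
    entropy = float(-(flat[nzp] * np.log2(flat[nzp])).sum())

    p_diff = np.bincount(absdiff_idx, weights=flat, minlength=Ng)
    k_diff = np.arange(p_diff.size, dtype=float)
    mu_d = float(k_diff @ p_diff)
    dif_varnc = float(((k_diff - mu_d) ** 2) @ p_diff)
    nzd = p_diff > 0
    dif_entrp = float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum())

    return {"AngScMom": asm, "Contrast": contrast, "Correlat": correlat,
            "SumOfSqs": sum_of_sqs, "InvDfMom": inv_df_mom,
            "SumAverg": sum_averg, "SumVarnc": sum_varnc,
            "SumEntrp": sum_entrp, "Entropy": entropy,
            "DifVarnc": dif_varnc, "DifEntrp": dif_entrp}


def glcm_direction_average(per_direction: List[Dict[str, float]]
                           ) -> Dict[str, float]:
    """Arithmetic mean of GLCM features across the four directions."""
    if not per_direction:
        raise ValueError("no direction features to average")
    keys = per_direction[0].keys()
    return {k: float(np.mean([f[k] for f in per_direction])) for k in keys}


# ---------------------------------------------------------------------------
# run-length matrix

@dataclass
class GLRLMatrix:
    """Run-length decomposition along one direction.

    Runs are maximal streaks of equal level along in-mask collinear segments
    (a mask break ends a run).  The dense ``matrix`` is built on demand.
    """

    run_levels: np.ndarray
    run_lengths: np.ndarray
    n_pixels: int
    Ng: int
    direction: int

    @property
    def n_runs(self) -> int:
        return int(self.run_levels.size)

    @property
    def matrix(self) -> np.ndarray:
        lmax = int(self.run_lengths.max()) if self.n_runs else 1
        out = np.zeros((self.Ng, lmax))
        np.add.at(out, (self.run_levels - 1, self.run_lengths - 1), 1)
        return out


def _direction_lines(v: np.ndarray, direction: int) -> List[np.ndarray]:
    R, C = v.shape
    if direction == 0:
        return [v[r] for r in range(R)]
    if direction == 90:
        return [v[:, c] for c in range(C)]
    if direction == 45:   # main diagonal, offset (1, 1)
        return [np.diagonal(v, k) for k in range(-(R - 1), C)]
    if direction == 135:  # anti-diagonal, offset (1, -1)
        w = np.fliplr(v)
        return [np.diagonal(w, k) for k in range(-(R - 1), C)]
    raise ValueError(f"direction must be one of {sorted(_OFFSETS)}")


def glrlm_compute(d: DiscretizedImage, direction: int) -> GLRLMatrix:
    """Scan maximal equal-level runs along one direction inside the mask."""
    if not d.mask.any():
        raise ValueError("empty mask")
    v = np.where(d.mask, d.levels, -1)
    lines = _direction_lines(v, direction)
    arr = np.concatenate([np.append(line, -1) for line in lines])
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    lv = arr[starts]
    keep = lv > 0
    return GLRLMatrix(run_levels=lv[keep].astype(np.int64),
                      run_lengths=(ends - starts)[keep].astype(np.int64),
                      n_pixels=int(d.mask.sum()), Ng=d.n_bins,
                      direction=direction)


def glrlm_features(m: GLRLMatrix) -> Dict[str, float]:
    """Short/long run emphasis, gray-level/run-length nonuniformity, fraction."""
    if m.n_runs == 0:
        raise ValueError("no runs")
    L = m.run_lengths.astype(float)
    nr = m.n_runs
    g_counts = np.bincount(m.run_levels)
    l_counts = np.bincount(m.run_lengths)
    return {
        "ShrtREmp": float((1.0 / L ** 2).mean()),
        "LngREmph": float((L ** 2).mean()),
        "GLevNonUni": float((g_counts.astype(float) ** 2).sum() / nr),
        "RLNonUni": float((l_counts.astype(float) ** 2).sum() / nr),
        "Fraction": nr / m.n_pixels,
    }


# ---------------------------------------------------------------------------
# wavelet

def wavelet_features(d: DiscretizedImage,
                     scales=WAVELET_SCALES
                     ) -> Tuple[Dict[str, float], Dict[str, bool]]:
    """Haar multiresolution subband energies over the mask bounding box.

    Out-of-mask pixels in the bounding box are filled with the in-mask mean.
    At each scale the running approximation is decomposed (periodization
    mode) and the mean squared coefficient of each subband recorded.  Subband
    naming: first letter is the filter along rows (axis 0), second along
    columns, so ``WavEnHL`` is high-pass down the rows.  Scales deeper than
    the patch allows are emitted as 0 with validity False.
    """
    m = d.mask
    if not m.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    if (r1 - r0) < 2 or (c1 - c0) < 2:
        raise ValueError("mask bounding box must be at least 2x2")
    patch = d.levels[r0:r1, c0:c1].astype(float)
    sub_mask = m[r0:r1, c0:c1]
    patch[~sub_mask] = patch[sub_mask].mean()

    values: Dict[str, float] = {}
    validity: Dict[str, bool] = {}
    cur = patch
    for s in scales:
        if min(cur.shape) < 2:
            for band in WAVELET_SUBBANDS:
                values[f"{band}_s{s}"] = 0.0
                validity[f"{band}_s{s}"] = False
            continue
        cA, (cH, cV, cD) = pywt.dwt2(cur, "haar", mode="periodization")
        # pywt: cH is high-pass along axis 0 -> HL in our naming; cV -> LH
        for band, coef in (("WavEnLL", cA), ("WavEnLH", cV),
                           ("WavEnHL", cH), ("WavEnHH", cD)):
            values[f"{band}_s{s}"] = float((coef ** 2).mean())
            validity[f"{band}_s{s}"] = True
        cur = cA
    return values, validity


# ---------------------------------------------------------------------------
# full vector

@dataclass
class FeatureVector:
    """Named, ordered feature values with per-feature validity flags."""

    names: List[str]
    values: np.ndarray
    validity: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.names) == self.values.size == self.validity.size):
            raise ValueError("names/values/validity lengths differ")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return len(self.names)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def extract_all(image: np.ndarray, mask: np.ndarray,
                registry: FeatureRegistry | None = None,
                n_bins: int = 256) -> FeatureVector:
    """Normalize the ROI and evaluate every registry entry in manifest order."""
    registry = registry or default_registry()
    d = normalize_gray_levels(image, mask, n_bins=n_bins)
    families = {e.family for e in registry.entries}

    cell: Dict[str, Tuple[float, bool]] = {}

    if "hist" in families:
        for k, v in histogram_features(d).items():
            cell[f"hist.{k}"] = (v, True)
    if "grad" in families:
        for k, v in gradient_features(d).items():
            cell[f"grad.{k}"] = (v, True)
    if "ar" in families:
        for k, v in ar_features(d).items():
            cell[f"ar.{k}"] = (v, True)
    if "glcm" in families:
        for dist in DISTANCES:
            per_dir: List[Dict[str, float] | None] = []
            for direction in DIRECTIONS:
                try:
                    feats = glcm_features(glcm_compute(d, direction, dist))
                except NoPixelPairsError:
                    feats = None
                per_dir.append(feats)
                for k in GLCM_NAMES:
                    key = f"glcm.{k}.d{direction}.dist{dist}"
                    cell[key] = (feats[k], True) if feats else (0.0, False)
            if all(f is not None for f in per_dir):
                avg = glcm_direction_average(per_dir)
                for k in GLCM_NAMES:
                    cell[f"glcm.{k}.avg.dist{dist}"] = (avg[k], True)
            else:
                for k in GLCM_NAMES:
                    cell[f"glcm.{k}.avg.dist{dist}"] = (0.0, False)
    if "glrlm" in families:
        for direction in DIRECTIONS:
            feats = glrlm_features(glrlm_compute(d, direction))
            for k, v in feats.items():
                cell[f"glrlm.{k}.d{direction}"] = (v, True)
    if "wav" in families:
        wv, wvalid = wavelet_features(d)
        for key, v in wv.items():
            band, s = key.rsplit("_", 1)
            cell[f"wav.{band}.{s}"] = (v, wvalid[key])

    values = np.empty(len(registry))
    valid = np.empty(len(registry), dtype=bool)
    names = registry.names
    for idx, name in enumerate(names):
        if name not in cell:
            raise KeyError(f"registry entry {name!r} was not computed")
        values[idx], valid[idx] = cell[name]
    return FeatureVector(names=names, values=values, validity=valid)


def feature_table(phantoms, registry: FeatureRegistry | None = None,
                  n_bins: int = 256,
                  masks=None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Feature matrix (rows = patients) plus matching validity flags.

    ``masks`` optionally overrides each phantom's own ROI (e.g. perturbed
    second-reader contours).
    """
    registry = registry or default_registry()
    rows, flags, ids = [], [], []
    for k, ph in enumerate(phantoms):
        mask = ph.mask if masks is None else masks[k]
        fv = extract_all(ph.pre_image, mask, registry=registry, n_bins=n_bins)
        rows.append(fv.values)
        flags.append(fv.validity)
        ids.append(ph.patient_id)
    values = pd.DataFrame(rows, index=ids, columns=registry.names)
    values.index.name = "patient_id"
    validity = pd.DataFrame(flags, index=ids, columns=registry.names)
    validity.index.name = "patient_id"
    return values, validity
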