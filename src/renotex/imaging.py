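"""Gray-level discretization and traditional radiological measurements.

Texture analysis operates on a fixed number of gray levels (default 256) so
that images from different scanners are comparable.  Discretization windows
the in-mask Hounsfield values at mean +/- ``sigma_mult`` SD and maps the
window linearly onto integer levels ``1..n_bins`` (half-open bins, top edge
closed).  The traditional block measures tri-axial tumor size, pre- and
post-contrast density (via small circular ROIs placed on solid tissue, three
repeats averaged), enhancement, and the derived T stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import TumorPhantom

__all__ = [
    "DiscretizedImage",
    "TraditionalFeatures",
    "normalize_gray_levels",
    "select_representative_slice",
    "measure_tumor_size",
    "measure_density",
    "compute_enhancement",
    "traditional_features",
    "traditional_features_table",
]

OUTSIDE = 0  # sentinel level for out-of-mask pixels


@dataclass
class DiscretizedImage:
    """ROI pixels mapped to integer levels 1..n_bins; 0 outside the mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    window: Tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        inm = self.levels[self.mask]
        if inm.size and (inm.min() < 1 or inm.max() > self.n_bins):
            raise ValueError("in-mask levels outside [1, n_bins]")

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def normalize_gray_levels(image: np.ndarray, mask: np.ndarray,
                          n_bins: int = 256,
                          sigma_mult: float = 3.0) -> DiscretizedImage:
    """Discretize in-mask intensities to ``1..n_bins`` inside a mu±k·sigma window.

    Values at or below the window floor map to level 1, values at or above
    the ceiling to ``n_bins``.  A constant ROI (sigma = 0) maps every pixel
    to the mid level ``ceil(n_bins / 2)``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(image, float)[mask]
    mu = vals.mean()
    sigma = vals.std()
    levels = np.zeros(mask.shape, dtype=np.int32)
    if sigma == 0:
        levels[mask] = int(math.ceil(n_bins / 2))
        window = (mu, mu)
    else:
        lo = mu - sigma_mult * sigma
        hi = mu + sigma_mult * sigma
        clipped = np.clip(vals, lo, hi)
        lv = np.floor((clipped - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
        np.clip(lv, 1, n_bins, out=lv)  # closes the top edge (hi -> n_bins)
        levels[mask] = lv
        window = (lo, hi)
    return DiscretizedImage(levels=levels, mask=mask, n_bins=n_bins,
                            window=window)


def select_representative_slice(volume: np.ndarray, mask3d: np.ndarray
                                ) -> Tuple[np.ndarray, np.ndarray]:
    """Pick the axial slice with the largest tumor cross-section.

    Slices are indexed along axis 0; ties are broken by the lowest index.
    """
    mask3d = np.asarray(mask3d, bool)
    if not mask3d.any():
        raise ValueError("empty 3D mask")
    areas = mask3d.reshape(mask3d.shape[0], -1).sum(axis=1)
    k = int(np.argmax(areas))  # argmax returns the first (lowest) maximizer
    return np.asarray(volume)[k], mask3d[k]


def measure_tumor_size(mask: np.ndarray, spacing_mm: float = 1.0,
                       craniocaudal_cm: Optional[float] = None,
                       n_repeats: int = 3
                       ) -> Tuple[float, float, Optional[float]]:
    """Bounding-box tumor dimensions in cm (transverse, AP, craniocaudal).

    Transverse is the column extent, anteroposterior the row extent
    (pixel-count extents, ``max - min + 1``).  The craniocaudal dimension is
    carried as metadata for 2D phantoms.  Mirroring the triplicate-measurement
    protocol, the measurement is repeated ``n_repeats`` times and averaged
    (identical on deterministic masks).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(mask)
    measurements = []
    for _ in range(n_repeats):
        ap = (rows.max() - rows.min() + 1) * spacing_mm / 10.0
        tr = (cols.max() - cols.min() + 1) * spacing_mm / 10.0
        measurements.append((tr, ap))
    tr = float(np.mean([m[0] for m in measurements]))
    ap = float(np.mean([m[1] for m in measurements]))
    return tr, ap, craniocaudal_cm


def measure_density(image: np.ndarray, mask: np.ndarray,
                    solid_mask: Optional[np.ndarray] = None,
                    roi_area_cm2: Tuple[float, float] = (0.2, 1.0),
                    n_repeats: int = 3, spacing_mm: float = 1.0,
                    seed: int = 0,
                    rois: Optional[list] = None,
                    return_rois: bool = False):
    """Mean HU from small circular ROIs placed on solid tumor tissue.

    Each of ``n_repeats`` seeded ROIs is a disk with area drawn uniformly from
    ``roi_area_cm2`` whose footprint lies fully inside the solid (necrosis-
    free) region; the per-ROI mean HU values are averaged.  Pass ``rois`` (a
    list of (row, col, radius_px) triples from a previous call) to re-measure
    the same locations, e.g. on the post-contrast image.
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    solid = mask if solid_mask is None else (np.asarray(solid_mask, bool) & mask)
    rng = np.random.default_rng(seed)
    rr_grid, cc_grid = np.indices(mask.shape)

    def disk_mean(r0: int, c0: int, rad: float) -> float:
        d = (rr_grid - r0) ** 2 + (cc_grid - c0) ** 2 <= rad ** 2
        return float(image[d].mean())

    if rois is not None:
        return float(np.mean([disk_mean(r, c, rad) for r, c, rad in rois]))

    placed = []
    vals = []
    for _ in range(n_repeats):
        area = rng.uniform(*roi_area_cm2)
        rad_px = math.sqrt(area / math.pi) * 10.0 / spacing_mm
        erosion = int(math.ceil(rad_px))
        allowed = ndimage.binary_erosion(solid, iterations=erosion) \
            if erosion > 0 else solid
        if not allowed.any():
            # retry at the smallest permitted ROI before giving up
            rad_px = math.sqrt(roi_area_cm2[0] / math.pi) * 10.0 / spacing_mm
            allowed = ndimage.binary_erosion(
                solid, iterations=int(math.ceil(rad_px)))
            if not allowed.any():
                raise ValueError("solid region too small for the density ROI")
        rows, cols = np.nonzero(allowed)
        k = rng.integers(0, len(rows))
        placed.append((int(rows[k]), int(cols[k]), rad_px))
        vals.append(disk_mean(rows[k], cols[k], rad_px))
    mean_hu = float(np.mean(vals))
    return (mean_hu, placed) if return_rois else mean_hu


def compute_enhancement(ct_pre: float, ct_post: float) -> float:
    """Contrast enhancement in HU (post minus pre)."""
    return ct_post - ct_pre


def _t_stage(max_dim_cm: float) -> str:
    """T1 for tumors up to 7 cm in greatest dimension, T2 beyond."""
    return "T1" if max_dim_cm <= 7.0 else "T2"


@dataclass
class TraditionalFeatures:
    """The human-visible radiological block for one patient."""

    patient_id: str
    transverse_cm: float
    anteroposterior_cm: float
    craniocaudal_cm: float
    ct_pre_hu: float
    ct_post_hu: float
    enhancement_hu: float
    t_stage: str

    def as_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "transverse_cm": self.transverse_cm,
            "anteroposterior_cm": self.anteroposterior_cm,
            "craniocaudal_cm": self.craniocaudal_cm,
            "ct_pre_hu": self.ct_pre_hu,
            "ct_post_hu": self.ct_post_hu,
            "enhancement_hu": self.enhancement_hu,
            "t_stage": self.t_stage,
        }


def traditional_features(phantom: TumorPhantom, seed: int = 0
                         ) -> TraditionalFeatures:
    """Measure the traditional radiological block on one phantom.

    Pre- and post-contrast densities are measured at the same seeded ROI
    locations so that enhancement reflects the paired difference.
    """
    tr, ap, cc = measure_tumor_size(phantom.mask, phantom.spacing_mm,
                                    craniocaudal_cm=phantom.sizes_true_cm[2])
    ct_pre, rois = measure_density(phantom.pre_image, phantom.mask,
                                   solid_mask=phantom.solid_mask,
                                   spacing_mm=phantom.spacing_mm, seed=seed,
                                   return_rois=True)
    ct_post = measure_density(phantom.post_image, phantom.mask,
                              solid_mask=phantom.solid_mask,
                              spacing_mm=phantom.spacing_mm, rois=rois)
    return TraditionalFeatures(
        patient_id=phantom.patient_id,
        transverse_cm=tr,
        anteroposterior_cm=ap,
        craniocaudal_cm=cc,
        ct_pre_hu=ct_pre,
        ct_post_hu=ct_post,
        enhancement_hu=compute_enhancement(ct_pre, ct_post),
        t_stage=_t_stage(max(tr, ap, cc if cc is not None else 0.0)),
    )


def traditional_features_table(phantoms, seed: int = 0) -> pd.DataFrame:
    """Traditional-feature CSV table, one row per phantom."""
    rng = np.random.default_rng(seed)
    rows = []
    for ph in phantoms:
        sub = int(rng.integers(0, 2 ** 31))
        rows.append(traditional_features(ph, seed=sub).as_row())
    return pd.DataFrame(rows)
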