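"""Synthetic renal-tumor phantom generator and cohort assembly.

Each phantom is a 2D axial slice in Hounsfield units: an elliptical tumor of
grade-dependent size on a uniform parenchyma background, with a Gaussian
random-field texture, optional necrotic foci (high grade), and a paired
post-contrast image in which solid tumor tissue enhances by a grade-dependent
amount.  All randomness is driven by explicit integer seeds so that a phantom
is a pure function of (grade, params, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .params import (
    GradeLabel,
    GradeParams,
    GroupDistributionParams,
    LogNormalSpec,
    default_params,
)

__all__ = [
    "TumorPhantom",
    "CohortAssignment",
    "generate_phantom",
    "generate_cohort",
    "split_cohort",
    "perturb_mask",
    "dice",
]


@dataclass
class TumorPhantom:
    """One synthetic patient: image pair, ROI mask, spacing and ground truth."""

    patient_id: str
    pre_image: np.ndarray
    post_image: np.ndarray
    mask: np.ndarray
    spacing_mm: float
    grade: GradeLabel
    sizes_true_cm: Tuple[float, float, float]  # transverse, AP, craniocaudal
    necrosis_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("phantom mask is empty")
        if self.mask.shape != self.pre_image.shape:
            raise ValueError("mask/image shape mismatch")
        if self.necrosis_mask is None:
            self.necrosis_mask = np.zeros_like(self.mask)

    @property
    def solid_mask(self) -> np.ndarray:
        """Tumor pixels excluding necrosis; the region that enhances."""
        return self.mask & ~self.necrosis_mask


@dataclass(frozen=True)
class CohortAssignment:
    patient_id: str
    cohort: str  # "training" | "validation"


def _sample_lognormal(spec: LogNormalSpec, rng: np.random.Generator) -> float:
    """Draw from a log-normal pinned at the median and truncated to the range."""
    mu = math.log(spec.median)
    if spec.max > spec.min:
        sigma = (math.log(spec.max) - math.log(spec.min)) / 4.0
    else:
        sigma = 0.0
    for _ in range(200):
        x = float(np.exp(rng.normal(mu, sigma)))
        if spec.min <= x <= spec.max:
            return x
    return float(np.clip(np.exp(rng.normal(mu, sigma)), spec.min, spec.max))


def _random_field(shape: Tuple[int, int], corr_len: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean random field with the requested correlation length."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=corr_len, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _paint_necrosis(mask: np.ndarray, gp: GradeParams,
                    rng: np.random.Generator) -> np.ndarray:
    het = gp.heterogeneity
    necrosis = np.zeros_like(mask)
    if het.necrosis_blob_count == 0 or het.necrosis_fraction == 0:
        return necrosis
    area = mask.sum()
    blob_area = het.necrosis_fraction * area / het.necrosis_blob_count
    radius = max(1.5, math.sqrt(blob_area / math.pi))
    # keep blob centers away from the rim so necrosis stays intratumoral
    interior = ndimage.binary_erosion(mask, iterations=max(1, int(radius)))
    rows, cols = np.nonzero(interior if interior.any() else mask)
    for _ in range(het.necrosis_blob_count):
        k = rng.integers(0, len(rows))
        ecc = rng.uniform(0.6, 1.0)
        rr, cc = draw_ellipse(rows[k], cols[k], radius, radius * ecc,
                              shape=mask.shape, rotation=rng.uniform(0, math.pi))
        necrosis[rr, cc] = True
    return necrosis & mask


def generate_phantom(grade: GradeLabel,
                     params: GroupDistributionParams | None = None,
                     seed: int = 0,
                     patient_id: str | None = None) -> TumorPhantom:
    """Generate one seeded tumor phantom of the given grade.

    The in-mask mean of the pre-contrast image is an exact realisation of the
    group's CT-pre normal distribution: texture and necrosis are painted first
    and the image is then re-centred so the whole-ROI mean equals the sampled
    draw.  Raises ``ValueError`` if the sampled tumor cannot fit on the canvas.
    """
    grade = GradeLabel(grade)
    params = params or default_params()
    gp = params.for_grade(grade)
    rng = np.random.default_rng(seed)
    shape = tuple(params.canvas_px)

    tr_cm = _sample_lognormal(gp.transverse_cm, rng)
    ap_cm = _sample_lognormal(gp.anteroposterior_cm, rng)
    cc_cm = _sample_lognormal(gp.craniocaudal_cm, rng)

    # semi-axes in pixels; transverse runs along columns, AP along rows
    a_col = tr_cm * 10.0 / params.spacing_mm / 2.0
    a_row = ap_cm * 10.0 / params.spacing_mm / 2.0
    if 2 * max(a_row, a_col) > min(shape) - 2:
        raise ValueError(
            f"sampled tumor ({tr_cm:.1f}x{ap_cm:.1f} cm) exceeds the "
            f"{shape[0]}x{shape[1]} px canvas at {params.spacing_mm} mm/px"
        )
    angle = rng.uniform(0.0, math.pi)
    center = (shape[0] / 2.0, shape[1] / 2.0)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(center[0], center[1], a_row, a_col,
                          shape=shape, rotation=angle)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("degenerate tumor: empty mask")

    ct_mean = rng.normal(gp.ct_pre_hu.mean, gp.ct_pre_hu.sd)
    enhancement = _sample_lognormal(gp.enhancement_hu, rng)

    pre = np.full(shape, params.background_hu, dtype=float)
    texture = _random_field(shape, gp.heterogeneity.correlation_length_px, rng)
    in_mask_tex = texture[mask]
    sd = in_mask_tex.std()
    if sd > 0 and gp.heterogeneity.texture_sd_hu > 0:
        tex_vals = (in_mask_tex - in_mask_tex.mean()) / sd \
            * gp.heterogeneity.texture_sd_hu
    else:
        tex_vals = np.zeros(in_mask_tex.shape)
    pre[mask] = ct_mean + tex_vals

    necrosis = _paint_necrosis(mask, gp, rng)
    if necrosis.any():
        pre[necrosis] += gp.heterogeneity.necrosis_offset_hu
        # re-centre so the whole-ROI mean stays the sampled CT-pre draw
        pre[mask] += ct_mean - pre[mask].mean()

    post = pre.copy()
    solid = mask & ~necrosis
    post[solid] += enhancement

    return TumorPhantom(
        patient_id=patient_id or f"phantom-{grade.value}-{seed}",
        pre_image=pre,
        post_image=post,
        mask=mask,
        spacing_mm=params.spacing_mm,
        grade=grade,
        sizes_true_cm=(tr_cm, ap_cm, cc_cm),
        necrosis_mask=necrosis,
    )


def generate_cohort(n_low: int = 206, n_high: int = 58,
                    params: GroupDistributionParams | None = None,
                    seed: int = 0
                    ) -> Tuple[List[TumorPhantom], pd.DataFrame]:
    """Generate a full synthetic cohort with a deterministic truth table.

    Per-patient sub-seeds are spawned from the master seed via
    ``numpy.random.SeedSequence`` so any patient can be regenerated alone.
    """
    if n_low < 0 or n_high < 0:
        raise ValueError("cohort counts must be nonnegative")
    params = params or default_params()
    n = n_low + n_high
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n)]
    phantoms: List[TumorPhantom] = []
    rows = []
    grades = [GradeLabel.low] * n_low + [GradeLabel.high] * n_high
    for i, (grade, sub) in enumerate(zip(grades, child_seeds)):
        pid = f"P{i + 1:04d}"
        ph = generate_phantom(grade, params, seed=sub, patient_id=pid)
        phantoms.append(ph)
        rows.append({
            "patient_id": pid,
            "grade": grade.value,
            "seed": sub,
            "transverse_cm": ph.sizes_true_cm[0],
            "anteroposterior_cm": ph.sizes_true_cm[1],
            "craniocaudal_cm": ph.sizes_true_cm[2],
        })
    truth = pd.DataFrame(rows, columns=["patient_id", "grade", "seed",
                                        "transverse_cm", "anteroposterior_cm",
                                        "craniocaudal_cm"])
    return phantoms, truth


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_cohort(ids: Sequence[str], labels: Sequence[GradeLabel | str],
                 ratio_train: float = 0.75, seed: int = 0,
                 stratified: bool = True) -> List[CohortAssignment]:
    """Randomly partition a cohort into training and validation sets.

    The total training count is ``round_half_up(ratio_train * n)`` (exactly
    3:1 at the default), apportioned across grade strata by largest remainder
    with ties broken toward the larger stratum; membership within each stratum
    is a seeded permutation draw.
    """
    ids = list(ids)
    labels = [GradeLabel(l).value for l in labels]
    if len(ids) != len(labels):
        raise ValueError("ids and labels differ in length")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if not (0.0 < ratio_train < 1.0):
        raise ValueError("ratio_train must lie strictly in (0, 1)")

    rng = np.random.default_rng(seed)
    strata: dict[str, list[int]] = {}
    if stratified:
        for i, lab in enumerate(labels):
            strata.setdefault(lab, []).append(i)
    else:
        strata["all"] = list(range(len(ids)))

    forced_train: list[int] = []
    eligible: dict[str, list[int]] = {}
    for name, members in strata.items():
        if len(members) < 2:
            warnings.warn(
                f"stratum {name!r} has fewer than 2 members; assigned to training")
            forced_train.extend(members)
        else:
            eligible[name] = members

    n_elig = sum(len(m) for m in eligible.values())
    n_train = _round_half_up(ratio_train * n_elig)
    # largest-remainder apportionment of training seats across strata
    names = sorted(eligible, key=lambda s: -len(eligible[s]))
    quotas = {s: ratio_train * len(eligible[s]) for s in names}
    alloc = {s: int(math.floor(quotas[s])) for s in names}
    leftovers = sorted(names, key=lambda s: (-(quotas[s] - alloc[s]),
                                             -len(eligible[s])))
    for s in leftovers:
        if sum(alloc.values()) >= n_train:
            break
        alloc[s] += 1
    while sum(alloc.values()) > n_train:  # can happen only for odd ratios
        s = min(names, key=lambda s: (quotas[s] - alloc[s], len(eligible[s])))
        alloc[s] -= 1

    train_idx = set(forced_train)
    for s in names:
        members = np.array(eligible[s])
        perm = rng.permutation(len(members))
        train_idx.update(members[perm[:alloc[s]]].tolist())
    return [CohortAssignment(ids[i],
                             "training" if i in train_idx else "validation")
            for i in range(len(ids))]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


def perturb_mask(mask: np.ndarray, magnitude: float, seed: int = 0) -> np.ndarray:
    """Simulate a second reader's contour by jittering the ROI boundary.

    The boundary is displaced by ``magnitude`` (pixels) along a seeded smooth
    random field added to the signed distance transform.  The perturbation
    field is fixed by the seed, so for a given seed the symmetric difference
    grows — and Dice decreases — monotonically with magnitude; magnitude 0 is
    the identity.
    """
    mask = np.asarray(mask, bool)
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    if magnitude == 0:
        return mask.copy()
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    signed = d_out - d_in  # negative inside, positive outside
    rng = np.random.default_rng(seed)
    fieldv = _random_field(mask.shape, corr_len=3.0, rng=rng)
    out = (signed + magnitude * fieldv) <= 0
    if not out.any():
        raise ValueError("perturbation emptied the mask")
    return out
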