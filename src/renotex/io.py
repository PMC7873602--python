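"""File I/O: NIfTI and 16-bit PNG (+ JSON sidecar) images, CSV tables."""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import TumorPhantom

__all__ = [
    "write_nifti", "read_nifti", "write_png16", "read_png16",
    "write_phantom", "read_phantom",
]


def write_nifti(path, image: np.ndarray, spacing_mm: float = 1.0,
                dtype=None) -> None:
    """Write a 2D image as NIfTI with the pixel spacing in the header."""
    data = np.asarray(image)
    if dtype is not None:
        data = data.astype(dtype)
    affine = np.diag([spacing_mm, spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data[..., None], affine), os.fspath(path))


def read_nifti(path) -> Tuple[np.ndarray, float]:
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[..., 0]
    spacing = float(img.header.get_zooms()[0])
    return data, spacing


def write_png16(path, image: np.ndarray, spacing_mm: float = 1.0,
                intercept: Optional[float] = None) -> None:
    """16-bit PNG with a JSON sidecar recording spacing and HU intercept.

    Hounsfield values can be negative; ``intercept`` (default: the image
    minimum, floored) shifts them into the unsigned range.
    """
    import imageio.v3 as iio

    image = np.asarray(image, float)
    if intercept is None:
        intercept = float(np.floor(image.min()))
    shifted = np.round(image - intercept)
    if shifted.min() < 0 or shifted.max() > 65535:
        raise ValueError("image does not fit a 16-bit range after shifting")
    iio.imwrite(os.fspath(path), shifted.astype(np.uint16))
    sidecar = Path(os.fspath(path)).with_suffix(".json")
    sidecar.write_text(json.dumps({"spacing_mm": spacing_mm,
                                   "intercept": intercept}))


def read_png16(path) -> Tuple[np.ndarray, float]:
    import imageio.v3 as iio

    raw = iio.imread(os.fspath(path)).astype(float)
    sidecar = Path(os.fspath(path)).with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return raw + meta["intercept"], float(meta["spacing_mm"])


def write_phantom(directory, phantom: TumorPhantom,
                  fmt: str = "nifti") -> None:
    """Write one phantom's image pair and masks under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pid = phantom.patient_id
    if fmt == "nifti":
        write_nifti(d / f"{pid}_pre.nii.gz", phantom.pre_image,
                    phantom.spacing_mm)
        write_nifti(d / f"{pid}_post.nii.gz", phantom.post_image,
                    phantom.spacing_mm)
        write_nifti(d / f"{pid}_mask.nii.gz",
                    phantom.mask.astype(np.uint8), phantom.spacing_mm)
        write_nifti(d / f"{pid}_necrosis.nii.gz",
                    phantom.necrosis_mask.astype(np.uint8),
                    phantom.spacing_mm)
    elif fmt == "png":
        write_png16(d / f"{pid}_pre.png", phantom.pre_image,
                    phantom.spacing_mm)
        write_png16(d / f"{pid}_post.png", phantom.post_image,
                    phantom.spacing_mm)
        write_png16(d / f"{pid}_mask.png",
                    phantom.mask.astype(float), phantom.spacing_mm,
                    intercept=0.0)
        write_png16(d / f"{pid}_necrosis.png",
                    phantom.necrosis_mask.astype(float),
                    phantom.spacing_mm, intercept=0.0)
    else:
        raise ValueError("fmt must be 'nifti' or 'png'")


def read_phantom(directory, patient_id: str, grade,
                 sizes_true_cm=(float("nan"),) * 3,
                 fmt: str = "nifti") -> TumorPhantom:
    d = Path(directory)
    if fmt == "nifti":
        pre, spacing = read_nifti(d / f"{patient_id}_pre.nii.gz")
        post, _ = read_nifti(d / f"{patient_id}_post.nii.gz")
        mask, _ = read_nifti(d / f"{patient_id}_mask.nii.gz")
        nec, _ = read_nifti(d / f"{patient_id}_necrosis.nii.gz")
    else:
        pre, spacing = read_png16(d / f"{patient_id}_pre.png")
        post, _ = read_png16(d / f"{patient_id}_post.png")
        mask, _ = read_png16(d / f"{patient_id}_mask.png")
        nec, _ = read_png16(d / f"{patient_id}_necrosis.png")
    return TumorPhantom(patient_id=patient_id, pre_image=np.asarray(pre, float),
                        post_image=np.asarray(post, float),
                        mask=np.asarray(mask) > 0.5, spacing_mm=spacing,
                        grade=grade, sizes_true_cm=tuple(sizes_true_cm),
                        necrosis_mask=np.asarray(nec) > 0.5)
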