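"""Shared fixtures: small phantoms, discretized images and cohort frames."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from renotex import default_params, generate_phantom
from renotex.imaging import DiscretizedImage


@pytest.fixture(scope="session")
def low_phantom():
    return generate_phantom("low", default_params(), seed=11)


@pytest.fixture(scope="session")
def high_phantom():
    return generate_phantom("high", default_params(), seed=12)


@pytest.fixture()
def disk_image():
    """A deterministic discretized disk ROI with smooth structure."""
    rng = np.random.default_rng(5)
    shape = (40, 40)
    rr, cc = np.indices(shape)
    mask = (rr - 20) ** 2 + (cc - 20) ** 2 <= 14 ** 2
    base = 5 * np.sin(rr / 3.0) + 4 * np.cos(cc / 4.0) + rng.normal(0, 1, shape)
    lo, hi = base[mask].min(), base[mask].max()
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = np.clip(
        np.floor((base[mask] - lo) / (hi - lo + 1e-9) * 16).astype(int) + 1,
        1, 16)
    return DiscretizedImage(levels=levels, mask=mask, n_bins=16,
                            window=(float(lo), float(hi)))


def make_feature_frame(n=90, n_pos=24, n_texture=12, n_informative=3,
                       shift=1.5, seed=0):
    """Synthetic modeling frame: texture block + named traditional block."""
    rng = np.random.default_rng(seed)
    y = np.array(["low"] * (n - n_pos) + ["high"] * n_pos)
    tex = rng.normal(size=(n, n_texture))
    tex[y == "high", :n_informative] += shift
    trad_cols = ["transverse_cm", "anteroposterior_cm", "craniocaudal_cm",
                 "ct_pre_hu", "ct_post_hu", "enhancement_hu"]
    trad = rng.normal(size=(n, len(trad_cols)))
    trad[y == "high", 3] += shift  # ct_pre_hu carries signal
    idx = [f"P{i:03d}" for i in range(n)]
    X = pd.DataFrame(
        np.column_stack([tex, trad]),
        columns=[f"tex{i}" for i in range(n_texture)] + trad_cols,
        index=idx)
    return X, pd.Series(y, index=idx)
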