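"""Reader-agreement analysis via the intraclass correlation coefficient.

Intra-observer agreement compares two feature extractions by the same reader;
inter-observer agreement compares readers one and two.  The default model is
ICC(2,1) — two-way random effects, absolute agreement, single measurement —
the standard choice for reader-agreement studies; ICC(3,1) (two-way mixed,
consistency) is available as an option.

Qualitative bands: poor (<0.21), fair (0.21–0.40], moderate (0.40–0.60],
good (0.60–0.80], excellent (0.80–1.00]; an ICC above 0.75 is flagged as
good agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["ICCResult", "icc", "icc_2_1", "icc_category",
           "reproducibility_report"]


def icc(ratings: np.ndarray, model: str = "icc2") -> float:
    """ICC from an ``n_subjects x k_raters`` matrix.

    A matrix with zero total variance returns 1.0 by convention (trivial
    perfect agreement).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2D subjects-by-raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.isfinite(m).all():
        raise ValueError("non-finite ratings")
    grand = m.mean()
    sst = ((m - grand) ** 2).sum()
    if sst == 0:
        return 1.0
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if model == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("model must be 'icc2' or 'icc3'")
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def icc_2_1(ratings: np.ndarray) -> float:
    """Two-way random effects, absolute agreement, single measurement."""
    return icc(ratings, model="icc2")


def icc_category(value: float) -> str:
    """Map an ICC to its qualitative agreement band."""
    if not np.isfinite(value):
        raise ValueError("ICC must be finite")
    if value > 0.80:
        return "excellent"
    if value > 0.60:
        return "good"
    if value > 0.40:
        return "moderate"
    if value >= 0.21:
        return "fair"
    return "poor"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    category: str
    passes_0_75: bool

    @classmethod
    def from_value(cls, value: float) -> "ICCResult":
        return cls(icc=value, category=icc_category(value),
                   passes_0_75=value > 0.75)


def reproducibility_report(features_reader1a: pd.DataFrame,
                           features_reader1b: pd.DataFrame,
                           features_reader2: pd.DataFrame,
                           icc_model: str = "icc2",
                           retention_threshold: Optional[float] = None
                           ) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Per-feature intra-/inter-observer ICC table plus the analysis set.

    Returns ``(report, analysis_features, retained_names)``.  The analysis
    set is always the Reader-1 first-pass extraction; ``retention_threshold``
    (e.g. 0.75) optionally restricts the retained feature list to those whose
    intra- and inter-observer ICCs both exceed it (off by default).
    """
    for other, tag in ((features_reader1b, "reader 1 repeat"),
                       (features_reader2, "reader 2")):
        if not features_reader1a.index.equals(other.index):
            raise ValueError(f"patient ids of {tag} do not match reader 1")
        if list(features_reader1a.columns) != list(other.columns):
            raise ValueError(f"feature columns of {tag} do not match reader 1")

    rows = []
    for col in features_reader1a.columns:
        intra = icc(np.column_stack([features_reader1a[col],
                                     features_reader1b[col]]), model=icc_model)
        inter = icc(np.column_stack([features_reader1a[col],
                                     features_reader2[col]]), model=icc_model)
        retained = True if retention_threshold is None else (
            intra > retention_threshold and inter > retention_threshold)
        rows.append({
            "feature_name": col,
            "icc_intra": intra,
            "icc_inter": inter,
            "category_intra": icc_category(np.clip(intra, -1, 1)),
            "category_inter": icc_category(np.clip(inter, -1, 1)),
            "retained": retained,
        })
    report = pd.DataFrame(rows).set_index("feature_name")
    retained_names = report.index[report["retained"]].tolist()
    return report, features_reader1a, retained_names
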