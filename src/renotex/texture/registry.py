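"""The texture-feature registry: a pinned, ordered manifest of feature names.

The default manifest emits exactly 340 features per ROI:

* histogram          11   (moments + nearest-rank percentiles)
* gradient            5
* autoregressive      5   (four causal coefficients + residual SD)
* co-occurrence     275   (11 features x 5 distances x (4 directions + avg))
* run-length         20   (5 features x 4 directions)
* wavelet            24   (4 Haar subband energies x 6 scales)

Feature identifiers follow ``family.name[.direction][.dist|.scale]``, e.g.
``glcm.Contrast.d45.dist2`` or ``wav.WavEnHH.s3``.  The manifest is versioned
and shipped as JSON (``registry_v1.json``) so every emitted value is auditable
and alternative compositions can be loaded from file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional

HIST_NAMES = ["Mean", "Variance", "Skewness", "Kurtosis", "Perc_01", "Perc_10",
              "Perc_25", "Perc_50", "Perc_75", "Perc_90", "Perc_99"]
GRAD_NAMES = ["GrMean", "GrVariance", "GrSkewness", "GrKurtosis", "GrNonZeros"]
AR_NAMES = ["Teta1", "Teta2", "Teta3", "Teta4", "Sigma"]
GLCM_NAMES = ["AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDfMom",
              "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc",
              "DifEntrp"]
GLRLM_NAMES = ["ShrtREmp", "LngREmph", "GLevNonUni", "RLNonUni", "Fraction"]
WAVELET_SUBBANDS = ["WavEnLL", "WavEnLH", "WavEnHL", "WavEnHH"]

DIRECTIONS = (0, 45, 90, 135)
DISTANCES = (1, 2, 3, 4, 5)
WAVELET_SCALES = (1, 2, 3, 4, 5, 6)

REGISTRY_VERSION = "v1"


@dataclass(frozen=True)
class FeatureSpec:
    """One registry entry."""

    family: str                      # hist | grad | ar | glcm | glrlm | wav
    name: str
    direction: Optional[str] = None  # "d0" ... "d135" or "avg"
    distance: Optional[int] = None   # glcm displacement in pixels
    scale: Optional[int] = None      # wavelet decomposition level

    @property
    def full_name(self) -> str:
        parts = [self.family, self.name]
        if self.direction is not None:
            parts.append(self.direction)
        if self.distance is not None:
            parts.append(f"dist{self.distance}")
        if self.scale is not None:
            parts.append(f"s{self.scale}")
        return ".".join(parts)


@dataclass
class FeatureRegistry:
    """Ordered feature manifest; evaluation follows this order exactly."""

    entries: List[FeatureSpec]
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")

    @property
    def names(self) -> List[str]:
        return [e.full_name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, families) -> "FeatureRegistry":
        fams = set(families)
        return FeatureRegistry(
            entries=[e for e in self.entries if e.family in fams],
            version=self.version + "-subset")

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "entries": [
                {k: v for k, v in e.__dict__.items() if v is not None}
                for e in self.entries
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FeatureRegistry":
        payload = json.loads(text)
        return cls(entries=[FeatureSpec(**e) for e in payload["entries"]],
                   version=payload["version"])


def default_registry() -> FeatureRegistry:
    """Build the default 340-feature manifest (deterministic order)."""
    entries: List[FeatureSpec] = []
    for name in HIST_NAMES:
        entries.append(FeatureSpec("hist", name))
    for name in GRAD_NAMES:
        entries.append(FeatureSpec("grad", name))
    for name in AR_NAMES:
        entries.append(FeatureSpec("ar", name))
    for dist in DISTANCES:
        for direction in [f"d{d}" for d in DIRECTIONS] + ["avg"]:
            for name in GLCM_NAMES:
                entries.append(FeatureSpec("glcm", name, direction=direction,
                                           distance=dist))
    for d in DIRECTIONS:
        for name in GLRLM_NAMES:
            entries.append(FeatureSpec("glrlm", name, direction=f"d{d}"))
    for scale in WAVELET_SCALES:
        for name in WAVELET_SUBBANDS:
            entries.append(FeatureSpec("wav", name, scale=scale))
    return FeatureRegistry(entries=entries)


def load_registry(path: Optional[str] = None) -> FeatureRegistry:
    """Load a registry manifest from file, or the packaged default."""
    if path is not None:
        with open(path) as fh:
            return FeatureRegistry.from_json(fh.read())
    text = resources.files("renotex.texture").joinpath(
        "registry_v1.json").read_text()
    return FeatureRegistry.from_json(text)
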