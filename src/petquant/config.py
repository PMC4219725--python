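"""Run configuration: one serializable object holding every tunable of the
pipeline, echoed verbatim (plus a hash) into each output directory."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    cohort_dir: str = ""
    output_dir: str = ""
    # VOI construction
    mask_fraction: float = 0.35       # threshold as fraction of map maximum
    psf_fwhm_mm: float = 8.0          # scanner PSF for spill-in erosion
    spillin_tau: float = 0.05         # max tolerated spill-in fraction
    reference_region: str = "thalamus_bilateral"
    # voxel-wise statistics
    smoothing_fwhm_mm: float = 12.0
    stats_forming_p: float = 0.001
    stats_n_perm: int = 5000
    stats_seed: int = 0
    stats_connectivity: int = 18
    stats_bonferroni_m: int = 9

    def __post_init__(self) -> None:
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction must be in (0, 1]")
        if not 0 <= self.spillin_tau < 1:
            raise ValueError("spillin_tau must be in [0, 1)")
        if self.stats_connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
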