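"""Run configuration shared by the library pipeline and the CLI.

All tunables of the denoising pipeline live in one serializable dataclass so
that a run can be reproduced from its emitted config echo plus the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented defaults.

    Rates/cutoffs are in Hz, windows in seconds; ``shrinkage`` is the
    trace-normalized diagonal-loading weight applied to every window
    covariance; detector parameters mirror the consensus artefact
    identification (MAD z-threshold, kneedle sensitivity, empirical-null
    iterations and significance level).
    """

    # preprocessing
    resample_fs: float = 256.0
    hp_cutoff: float = 1.0
    lp_cutoff: float = 40.0
    # covariance estimation
    window_s: float = 1.0
    shrinkage: float = 1e-6
    karcher_tol: float = 1e-8
    karcher_max_iter: int = 500
    # artefact identification
    mad_z: float = 3.0
    kneedle_sensitivity: float = 1.0
    null_b: int = 200
    alpha: float = 0.05
    # orchestration
    mode: str = "batch"  # "batch" | "stream"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resample_fs <= 0:
            raise ValueError("resample_fs must be positive")
        if not 0 < self.hp_cutoff < self.lp_cutoff:
            raise ValueError("need 0 < hp_cutoff < lp_cutoff")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if not 0 <= self.shrinkage < 1:
            raise ValueError("shrinkage must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.null_b < 1:
            raise ValueError("null_b must be >= 1")
        if self.mode not in ("batch", "stream"):
            raise ValueError("mode must be 'batch' or 'stream'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
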