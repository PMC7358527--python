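"""Run configuration: thresholds, design constants, YAML/JSON loading."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds and stochastic-stage settings.

    All tolerances are strictly positive; `seed` fixes every stochastic
    stage end to end.
    """

    seed: int = 0
    align_tol: float = 0.5  # nt, replicate peak alignment
    bin_tol: float = 0.5  # nt, cross-sample TRF binning
    minor_frac: float = 0.001  # minor-peak threshold (fraction of trace total)
    band_tol_frac: float = 0.02  # band-match tolerance (fraction of position)
    assumed_burst_size: float = 20.0  # viruses per lysed cell
    permutations: int = 999  # Monte Carlo permutations for the CCA test
    mds_restarts: int = 4

    def __post_init__(self) -> None:
        for name in ("align_tol", "bin_tol", "minor_frac", "band_tol_frac",
                     "assumed_burst_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.permutations < 99:
            raise ValueError("permutations must be at least 99")
        if self.mds_restarts < 1:
            raise ValueError("mds_restarts must be at least 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML or JSON; keyword overrides win over file values."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**data, **{k: v for k, v in overrides.items() if v is not None}}
        return cls(**merged)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
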