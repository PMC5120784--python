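"""Pipeline configuration: validated defaults for every tunable of the
analysis (band edges, window length, FDR level, permutation count, variance
threshold), loadable from YAML or JSON."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    band: tuple[float, float] = (0.06, 0.125)
    window_seconds: float = 60.0
    drop_boundary_windows: int = 0
    per_run_filter: bool = False
    fdr_alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    n_perm: int = 1000
    bonferroni_m: int | str = "auto"
    variance_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        object.__setattr__(self, "band", (float(low), float(high)))
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.drop_boundary_windows < 0:
            raise ValueError("drop_boundary_windows must be >= 0")
        if not 0 <= self.fdr_alpha <= 1:
            raise ValueError("fdr_alpha must lie in [0, 1]")
        if self.fdr_method not in ("fdr_bh", "fdr_by"):
            raise ValueError("fdr_method must be 'fdr_bh' or 'fdr_by'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if isinstance(self.bonferroni_m, str):
            if self.bonferroni_m != "auto":
                raise ValueError("bonferroni_m must be 'auto' or a positive integer")
        elif self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be 'auto' or a positive integer")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(mapping)
        if "band" in data:
            data["band"] = tuple(data["band"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            mapping = yaml.safe_load(text)
        else:
            mapping = json.loads(text)
        return cls.from_mapping(mapping or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(d["band"])
        return d
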