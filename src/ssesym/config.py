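"""Pipeline configuration: every decision threshold as a named key.

Defaults are the operating points of the detection rules: a circular
permutation needs a post-rearrangement TM-score >= 0.5 improving on the
original order by >= 0.1; an indel needs a cross-boundary gap of >= 40
residues or >= 60% of the smaller segment; self-scan and symmetry-by-split
use TM 0.5; overlapping self-scan candidates are consolidated with a 0.05
TM margin; chains need >= 5 SSEs to enter the pipeline and >= 3 SSEs per
repeat unit.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    cp_tm: float = 0.5
    cp_delta_tm: float = 0.1
    indel_min_gap: int = 40
    indel_frac: float = 0.6
    sym_tm: float = 0.5
    scan_tm: float = 0.5
    consolidate_delta: float = 0.05
    prescreen_threshold: float = 0.5
    min_sse: int = 5
    min_unit_sse: int = 3
    min_segment_length: int = 2
    token_cap: int = 60
    normalize_on: str = "shorter"
    matrix_path: str | None = None
    tmalign_bin: str | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        for key in ("cp_tm", "sym_tm", "scan_tm", "prescreen_threshold"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{key} must be in [0, 1], got {v}")
        if not 0.0 <= self.cp_delta_tm <= 1.0:
            raise ValueError("cp_delta_tm must be in [0, 1]")
        if self.indel_min_gap < 0:
            raise ValueError("indel_min_gap must be >= 0")
        if not 0.0 <= self.indel_frac <= 1.0:
            raise ValueError("indel_frac must be in [0, 1]")
        if self.min_sse < 1 or self.min_unit_sse < 1 or self.min_segment_length < 1:
            raise ValueError("SSE count thresholds must be >= 1")
        if self.normalize_on not in ("a", "b", "shorter"):
            raise ValueError("normalize_on must be one of a/b/shorter")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                lines.append(f"# {f.name} = <unset>")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"
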