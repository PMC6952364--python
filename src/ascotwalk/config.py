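"""Run configuration: every pipeline tunable in one validated record.

Loadable from YAML; CLI flags override file values. Unknown keys are
rejected so typos never silently fall back to defaults.
"""

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
    # junction loading
    min_intron_length: int = 20
    # event discovery
    min_reads: int = 5
    min_samples: int = 1
    mxe_noise_frac: float = 0.01
    max_linked: int = 3
    max_exon_span: int = 10_000
    # PSI quantification
    min_informative: int = 15
    psi_convention: str = "mean"
    # specificity calls
    threshold: float = 50.0
    min_group_n: int = 2
    min_groups_informative: int = 3
    # motif windows
    intronic_flank: int = 1000
    exonic_flank: int = 50
    bin_width: int = 25
    motif: str = "TAG"
    baseline_max_exon_len: int = 400
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.min_intron_length >= 1, "min_intron_length must be >= 1"),
            (self.min_reads >= 0, "min_reads must be >= 0"),
            (self.min_samples >= 0, "min_samples must be >= 0"),
            (0 <= self.mxe_noise_frac < 1, "mxe_noise_frac must be in [0, 1)"),
            (self.max_linked >= 2, "max_linked must be >= 2"),
            (self.max_exon_span >= 1, "max_exon_span must be >= 1"),
            (self.min_informative >= 0, "min_informative must be >= 0"),
            (self.psi_convention in ("mean", "sum", "min"), "psi_convention must be mean|sum|min"),
            (0 < self.threshold <= 100, "threshold must be in (0, 100]"),
            (self.min_group_n >= 1, "min_group_n must be >= 1"),
            (self.min_groups_informative >= 2, "min_groups_informative must be >= 2"),
            (self.intronic_flank >= 1, "intronic_flank must be >= 1"),
            (self.exonic_flank >= 1, "exonic_flank must be >= 1"),
            (self.bin_width >= 1, "bin_width must be >= 1"),
            (self.intronic_flank % self.bin_width == 0, "intronic_flank must be a multiple of bin_width"),
            (bool(self.motif), "motif must be non-empty"),
            (self.baseline_max_exon_len >= 2, "baseline_max_exon_len must be >= 2"),
            (self.seed >= 0, "seed must be >= 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def load(cls, path: str | os.PathLike | None = None, **overrides) -> "RunConfig":
        """Build from an optional YAML file plus keyword overrides."""
        values: dict = {}
        if path is not None:
            with open(path) as handle:
                loaded = yaml.safe_load(handle) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            unknown = sorted(set(loaded) - set(cls.field_names()))
            if unknown:
                raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
            values.update(loaded)
        overrides = {k: v for k, v in overrides.items() if v is not None}
        unknown = sorted(set(overrides) - set(cls.field_names()))
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        values.update(overrides)
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
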