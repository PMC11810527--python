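"""Pipeline configuration: parameters, ranges, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .clock import CI_HALF_WIDTH

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value is out of its documented range."""


@dataclass
class PipelineConfig:
    """All knobs of the simulate->process->call->age->summarize pipeline.

    Defaults reflect the study conditions: Q20 end-trimming with a 40 bp
    minimum length, quality-aware overlap merging, a 1,000x coverage QC
    floor for synthetic runs, the 4.47-year CI half-width, and 5-year
    age bins.
    """

    out_dir: str = "heaa_out"
    # cohort / simulation
    n_individuals: int = 21
    duplicate_pairs: int = 4
    sex_ratio: float = 15 / 21
    age_min: float = 2.0
    age_max: float = 31.0
    reads_per_gene: int = 2000
    error_rate: float = 0.0
    conversion_efficiency: float = 1.0
    seed: int = 0
    # read processing
    min_q: int = 20
    min_len: int = 40
    min_overlap: int = 10
    merge_max_mismatch_frac: float = 0.25
    # alignment / calling
    align_max_mismatch_frac: float = 0.1
    coverage_floor: int = 1000
    # reporting
    ci_half_width: float = CI_HALF_WIDTH
    bin_width: float = 5.0

    def __post_init__(self) -> None:
        checks = [
            (self.n_individuals >= 1, "n_individuals >= 1"),
            (0 <= self.duplicate_pairs <= self.n_individuals,
             "0 <= duplicate_pairs <= n_individuals"),
            (0.0 <= self.sex_ratio <= 1.0, "sex_ratio in [0, 1]"),
            (0.0 <= self.age_min <= self.age_max, "0 <= age_min <= age_max"),
            (self.reads_per_gene >= 1, "reads_per_gene >= 1"),
            (0.0 <= self.error_rate < 0.1, "error_rate in [0, 0.1)"),
            (0.0 <= self.conversion_efficiency <= 1.0,
             "conversion_efficiency in [0, 1]"),
            (self.min_q >= 0, "min_q >= 0"),
            (self.min_len >= 0, "min_len >= 0"),
            (self.min_overlap >= 1, "min_overlap >= 1"),
            (0.0 <= self.merge_max_mismatch_frac <= 1.0,
             "merge_max_mismatch_frac in [0, 1]"),
            (0.0 <= self.align_max_mismatch_frac <= 1.0,
             "align_max_mismatch_frac in [0, 1]"),
            (self.coverage_floor >= 1, "coverage_floor >= 1"),
            (self.ci_half_width >= 0, "ci_half_width >= 0"),
            (self.bin_width > 0, "bin_width > 0"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ConfigError("config out of range: " + "; ".join(bad))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
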