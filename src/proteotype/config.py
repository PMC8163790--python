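"""Pipeline configuration: every tunable threshold with its default.

Defaults encode the study conventions: 1/x^2 calibration weighting, 5%
above-LLOQ quantifiability, |r| >= 0.8 contamination clustering, sex
contrast at raw p < 0.01 and twofold change, knockout contrasts at
BH-adjusted p < 0.05 and twofold change.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    #: calibration weighting exponent e; weights are 1/x^e (2 -> 1/x^2)
    weighting_exponent: int = 2
    #: minimum fraction of all measurements in range for "quantifiable"
    detect_min_fraction: float = 0.05
    #: absolute correlation threshold for contamination clustering
    correlation_threshold: float = 0.8
    #: sex contrast: raw-p threshold and fold-change threshold
    sex_p_threshold: float = 0.01
    sex_fold_threshold: float = 2.0
    sex_use_adjusted_p: bool = False
    #: knockout contrasts: BH-adjusted p and fold-change thresholds
    ko_p_threshold: float = 0.05
    ko_fold_threshold: float = 2.0
    ko_use_adjusted_p: bool = True
    #: Benjamini-Hochberg adjustment on/off
    bh_adjust: bool = True
    #: contamination co-trending rule: fraction of other panel members that
    #: must shift with same sign and at least this |log2 FC|
    co_trend_fraction: float = 0.5
    co_trend_min_abs_log2fc: float = 0.5
    #: log base for fold changes
    log_base: float = 2.0
    #: stratified folds for the cross-validated classifier C-statistic
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weighting_exponent < 0:
            raise ConfigError("weighting_exponent must be >= 0")
        for name in ("detect_min_fraction", "correlation_threshold", "co_trend_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("sex_p_threshold", "ko_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in ("sex_fold_threshold", "ko_fold_threshold", "log_base"):
            if getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be > 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
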