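"""Run configuration: every threshold of the analysis in one place.

The on-disk dialect is a flat YAML mapping.  Unknown keys are rejected
outright — a silently ignored typo in a threshold is the main
reproducibility hazard in this kind of pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the staged MR analysis."""

    # instrument selection
    p_thresh: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    maf_min: float = 0.01
    maf_strict_missing: bool = False
    # harmonization
    palindrome_mode: str = "infer"     # "infer" or "drop"
    eaf_window: float = 0.08
    proxy_r2_min: float = 0.8
    proxy_window_kb: float = 250.0
    # estimators
    ivw_model: str = "auto"
    wald_se_order: str = "first"
    mbe_phi: float = 1.0
    n_boot: int = 1000
    raps_loss: str = "huber"
    raps_overdispersion: bool = True
    # MR-PRESSO
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05          # global-test escalation threshold
    presso_outlier_alpha: float = 0.05
    presso_outlier_criterion: str = "adjusted"  # "adjusted" or "raw"
    # staged workflow
    heterogeneity_alpha: float = 0.05   # step-3 escalation threshold
    step3_p_below: float = 1.0          # remove SNPs with outlier p below this
    bonferroni_alpha: float = 0.05
    n_methods: int = 5
    lead_method: str = "ivw"

    def __post_init__(self) -> None:
        if not (0 < self.p_thresh < 1):
            raise ConfigurationError("p_thresh must lie in (0, 1)")
        if self.palindrome_mode not in ("infer", "drop"):
            raise ConfigurationError(f"bad palindrome_mode {self.palindrome_mode!r}")
        if self.presso_outlier_criterion not in ("adjusted", "raw"):
            raise ConfigurationError(
                f"bad presso_outlier_criterion {self.presso_outlier_criterion!r}"
            )
        if self.ivw_model not in ("fixed", "random", "auto"):
            raise ConfigurationError(f"bad ivw_model {self.ivw_model!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def setup_logging(level: int = logging.INFO) -> None:
    """Structured stderr logging for CLI runs."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
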