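"""Pipeline configuration: every protocol constant in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .tiles import ScoringThresholds


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the analysis protocol.

    The defaults implement the study protocol: 60-month administrative
    right-censoring of overall survival, two-fold cross-validated Cox
    risk scores, discovery-median cutoff, a 1,000-permutation log-rank
    test, and exclusion of the micropapillary pattern from the feature
    aggregation.
    """

    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    censor_horizon_months: float = 60.0
    n_folds: int = 2
    n_permutations: int = 1000
    random_seed: int = 0
    exclude_micropapillary: bool = True
    #: which feature selection the survival model uses (see
    #: features.build_feature_matrix)
    feature_selection: str = "gps_tils"
    #: L2 penalty on Cox coefficients; keeps ~50-feature fits on ~200
    #: discovery patients well conditioned
    ridge: float = 0.1

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.censor_horizon_months <= 0:
            raise ValueError("censor_horizon_months must be > 0")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ScoringThresholds(**d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
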