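"""Pipeline configuration: YAML file + programmatic defaults, validated up front.

Precedence is command-line flags > config file > defaults.  The fully
resolved configuration is echoed into every output directory so results are
self-describing, and a single master seed deterministically derives the
seeds of every stochastic stage (model initialization, null-model rewiring,
cross-validation folds, data simulation).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .ndcn import NdcnConfig
from .synthetic import SyntheticSpec

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    window_length: int = 6
    window_step: int = 5
    coupling_density: float = 0.15
    binarize_density: float = 0.15
    n_random: int = 20
    n_swaps_per_edge: int = 10
    horizon: int = 70
    classifier: str = "svm"
    n_folds: int = 5
    seed: int = 0
    ndcn: NdcnConfig = field(default_factory=NdcnConfig)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.window_step < 1:
            raise ValueError("window_length and window_step must be >= 1")
        for name in ("coupling_density", "binarize_density"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.n_random < 1 or self.n_swaps_per_edge < 1:
            raise ValueError("n_random and n_swaps_per_edge must be >= 1")
        if self.classifier not in ("svm", "knn", "nb"):
            raise ValueError("classifier must be svm, knn or nb")

    # derived per-stage seeds (single master seed end-to-end)
    @property
    def seed_model(self) -> int:
        return self.seed

    @property
    def seed_metrics(self) -> int:
        return self.seed + 1

    @property
    def seed_classify(self) -> int:
        return self.seed + 2

    def resolved_ndcn(self) -> NdcnConfig:
        return replace(self.ndcn, seed=self.seed_model)

    def resolved_synthetic(self) -> SyntheticSpec:
        return replace(self.synthetic, seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    ndcn_raw = raw.pop("ndcn", {}) or {}
    synth_raw = raw.pop("synthetic", {}) or {}
    known = {f.name for f in fields(PipelineConfig)} - {"ndcn", "synthetic"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(
        ndcn=NdcnConfig(**ndcn_raw),
        synthetic=SyntheticSpec(**synth_raw),
        **raw,
    )


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
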