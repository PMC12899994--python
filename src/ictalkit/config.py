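"""Central YAML configuration for the pipeline.

Every numeric policy of the pipeline (band edges, notch width, window/hop,
balancing ratio, smoothing window, model list, synthetic-cohort parameters,
seed) lives in one mapping so a run is fully described by its config
snapshot.  ``validate_config`` reports all offending keys at once.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .models import MODEL_NAMES

__all__ = ["PipelineConfig", "load_config", "validate_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration; message lists the offending keys."""


@dataclass
class PipelineConfig:
    seed: int = 42
    run_dir: str = "runs"
    # synthetic cohort
    synth: dict = field(default_factory=dict)
    # preprocessing
    band_hz: tuple[float, float] = (0.5, 40.0)
    notch_width_hz: float = 2.0
    window_s: float = 5.0
    hop_s: float = 2.5
    # features
    include_overlap_frac: bool = False
    # modelling
    models: list[str] = field(default_factory=lambda: ["xgboost"])
    collinearity_threshold: float = 0.95
    sample_cap: int = 20000
    max_ratio: float = 20.0
    calibration_frac: float = 0.2
    smoothing_window: int = 5
    threshold: float = 0.5
    min_event_len: int = 3
    # explainability
    top_k: int = 10
    stability_k: int = 20

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d


def validate_config(cfg: PipelineConfig) -> None:
    problems: list[str] = []
    if cfg.smoothing_window % 2 == 0 or not 3 <= cfg.smoothing_window <= 11:
        problems.append("smoothing_window: must be odd and in [3, 11]")
    if not 0 < cfg.threshold < 1:
        problems.append("threshold: must lie in (0, 1)")
    if not 0 < cfg.calibration_frac < 1:
        problems.append("calibration_frac: must lie in (0, 1)")
    if not 0 < cfg.collinearity_threshold <= 1:
        problems.append("collinearity_threshold: must lie in (0, 1]")
    if cfg.max_ratio < 1:
        problems.append("max_ratio: must be >= 1")
    if cfg.min_event_len < 1:
        problems.append("min_event_len: must be >= 1")
    if not cfg.band_hz[0] < cfg.band_hz[1]:
        problems.append("band_hz: edges must increase")
    if cfg.window_s <= 0 or cfg.hop_s <= 0 or cfg.hop_s > cfg.window_s:
        problems.append("window_s/hop_s: need 0 < hop_s <= window_s")
    unknown = [m for m in cfg.models if m not in MODEL_NAMES]
    if unknown:
        problems.append(f"models: unknown names {unknown} (known: {MODEL_NAMES})")
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; missing keys take defaults."""
    cfg = PipelineConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = set(PipelineConfig.__dataclass_fields__)
        bad = [k for k in raw if k not in known]
        if bad:
            raise ConfigError(f"unknown config keys: {bad}")
        for k, v in raw.items():
            if k == "band_hz":
                v = tuple(float(x) for x in v)
            setattr(cfg, k, v)
    validate_config(cfg)
    return cfg
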