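"""YAML configuration loading for filters, featurization, training, acquisition."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curation import AlertSet, FilterConfig
from .featurize import FeaturizerSpec
from .ranker import TrainConfig
from .synthetic import OracleConfig


@dataclass
class AcquisitionConfig:
    """Knobs of the MC-dropout acquisition loop."""

    n_samples: int = 100
    dropout_rate: float = 0.2
    batch_size: int = 1000
    candidate_multiplier: int = 100   # candidates sampled per batch slot
    shared_mask: bool = True


@dataclass
class Config:
    """All tunables of the pipeline, loadable from one YAML file."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    featurizer: FeaturizerSpec = field(default_factory=FeaturizerSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    oracle: OracleConfig = field(default_factory=OracleConfig)


def load_config(path: str | Path | None) -> Config:
    """Build a Config from a YAML file; missing sections keep their defaults.

    The ``filters`` section accepts an ``alert_csv`` key pointing at a
    (name, SMARTS) CSV replacing the built-in alert set; the ``training``
    section accepts a ``hidden_sizes`` list.
    """
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "filters" in raw:
        opts = dict(raw["filters"])
        alert_csv = opts.pop("alert_csv", None)
        if alert_csv:
            opts["alert_set"] = AlertSet.from_csv(alert_csv)
        cfg.filters = FilterConfig(**opts)
    if "featurizer" in raw:
        opts = dict(raw["featurizer"])
        if "descriptor_names" in opts:
            opts["descriptor_names"] = tuple(opts["descriptor_names"])
        cfg.featurizer = FeaturizerSpec(**opts)
    if "training" in raw:
        opts = dict(raw["training"])
        if "hidden_sizes" in opts:
            opts["hidden_sizes"] = tuple(opts["hidden_sizes"])
        cfg.training = TrainConfig(**opts)
    if "acquisition" in raw:
        cfg.acquisition = AcquisitionConfig(**raw["acquisition"])
    if "oracle" in raw:
        cfg.oracle = OracleConfig(**raw["oracle"])
    return cfg
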