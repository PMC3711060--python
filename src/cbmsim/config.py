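"""Structured-text (YAML) round-trip for experiment configurations.

The schema mirrors the configuration dataclasses one-to-one: top-level
sections ``arm``, ``net``, ``loop``, ``teaching``, ``metric`` and
``protocol``, each a flat mapping of the corresponding dataclass fields
(nested LIF sections under ``net``). Unknown keys are rejected so typos
fail loudly.
"""

from __future__ import annotations

import dataclasses
import pathlib

import yaml

from .arm import ArmParams
from .loop import LoopConfig
from .metrics import MetricConfig
from .models import TeachingConfig
from .network import LIFConfig, MicrocomplexConfig
from .protocol import ProtocolConfig

_PROTOCOL_FIELDS = ("centre", "n_targets", "target_radius",
                    "trial_trajectories", "steps", "trials_per_step",
                    "bias_start_deg", "bias_increment_deg", "probe_bias_deg",
                    "consolidation_trials", "n_subjects")


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def protocol_to_yaml(cfg: ProtocolConfig, path) -> None:
    """Write a full experiment configuration as YAML."""
    doc = {
        "arm": _plain(cfg.arm),
        "net": _plain(cfg.net),
        "loop": _plain(cfg.loop),
        "teaching": _plain(cfg.teaching),
        "metric": _plain(cfg.metric),
        "protocol": {k: _plain(getattr(cfg, k)) for k in _PROTOCOL_FIELDS},
    }
    pathlib.Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _build(cls, mapping, nested=()):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in mapping.items():
        if k in nested:
            kwargs[k] = LIFConfig(**v)
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def protocol_from_yaml(path) -> ProtocolConfig:
    """Load an experiment configuration written by :func:`protocol_to_yaml`."""
    doc = yaml.safe_load(pathlib.Path(path).read_text())
    cfg = ProtocolConfig(
        arm=_build(ArmParams, doc.get("arm", {})),
        net=_build(MicrocomplexConfig, doc.get("net", {}),
                   nested=("lif_gc", "lif_pc", "lif_dcn")),
        loop=_build(LoopConfig, doc.get("loop", {})),
        teaching=_build(TeachingConfig, doc.get("teaching", {})),
        metric=_build(MetricConfig, doc.get("metric", {})),
    )
    proto = doc.get("protocol", {})
    unknown = set(proto) - set(_PROTOCOL_FIELDS)
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    for k, v in proto.items():
        setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
    cfg.validate()
    return cfg
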