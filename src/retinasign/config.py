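"""Run configuration: YAML keys, defaults, and reproducibility manifests.

Default constants (heuristically tuned reference values):

====================  =======  =========================================
key                   default  meaning
====================  =======  =========================================
beta_ph               0        photoreceptor gain control (DC gain 1/(1+b))
alpha_ph              1        spatial cut-off constant
tau_ph                1        temporal smoothing constant (frames)
v0                    0.7      adaptation compression parameter, in [0, 1]
vmax                  255      maximum pixel value (8-bit)
train.epochs          20       training epochs
train.batch_size      32
train.learning_rate   1e-3
train.optimizer       adam
seed                  0        master seed for all randomness
====================  =======  =========================================
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .adaptation import AdaptationParams
from .classifier import TrainConfig
from .retina import PhotoreceptorParams

__all__ = ["RunConfig", "load_config", "config_hash", "write_manifest"]


@dataclass
class RunConfig:
    photoreceptor: PhotoreceptorParams = field(default_factory=PhotoreceptorParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Flat keys (beta_ph, alpha_ph, tau_ph, v0, vmax, seed, log_level) and a
    nested ``train:`` mapping are recognized; unspecified keys fall back to
    the documented defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    ph = PhotoreceptorParams(
        beta_ph=float(data.get("beta_ph", 0.0)),
        alpha_ph=float(data.get("alpha_ph", 1.0)),
        tau_ph=float(data.get("tau_ph", 1.0)),
    )
    ad = AdaptationParams(
        v0=float(data.get("v0", 0.7)),
        vmax=float(data.get("vmax", 255.0)),
    )
    tr_raw = dict(data.get("train", {}))
    tr = TrainConfig(
        epochs=int(tr_raw.get("epochs", 20)),
        batch_size=int(tr_raw.get("batch_size", 32)),
        learning_rate=float(tr_raw.get("learning_rate", 1e-3)),
        optimizer=str(tr_raw.get("optimizer", "adam")),
        seed=int(tr_raw.get("seed", data.get("seed", 0))),
    )
    return RunConfig(
        photoreceptor=ph, adaptation=ad, train=tr,
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
    )


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(out_dir, cfg: RunConfig, inputs: dict, extra: dict | None = None) -> Path:
    """Record everything needed to reproduce a run (inputs, config hash,
    seed, counts) as ``manifest.json`` in the output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "inputs": inputs,
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
    }
    if extra:
        payload.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
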