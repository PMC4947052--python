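"""Pipeline configuration: YAML/JSON loading and deterministic hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import ArrayGeometry, ProtocolSpec, WindowSpec
from .detection import DetectionParams
from .synthetic import ResponseModel, make_response_model

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    seed: int = 0
    geometry: ArrayGeometry = field(default_factory=ArrayGeometry)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    synthetic: dict = field(default_factory=dict)
    alpha_bin: float = 0.05
    alpha_electrode: float = 0.001
    kmeans_seed: int = 0
    classifier_features: tuple[str, ...] = ("activation", "tsc", "first_bin")
    classifier_methods: tuple[str, ...] = ("kmeans", "kmeans_pc", "svc")
    svc_folds: int = 5
    spikes_path: str | None = None
    stims_path: str | None = None
    raw_path: str | None = None

    def build_model(self) -> ResponseModel:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("n_electrodes", self.geometry.n_electrodes)
        kwargs.setdefault("n_sites", self.protocol.n_sites)
        for key in ("selective_electrodes", "selective_bins"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "burst_interval" in kwargs:
            kwargs["burst_interval"] = tuple(kwargs["burst_interval"])
        if "block2_scale" in kwargs and kwargs["block2_scale"]:
            kwargs["block2_scale"] = {int(k): float(v) for k, v in kwargs["block2_scale"].items()}
        return make_response_model(window=self.window, **kwargs)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "geometry": asdict(self.geometry),
            "protocol": asdict(self.protocol),
            "window": asdict(self.window),
            "detection": asdict(self.detection),
            "synthetic": self.synthetic,
            "alpha_bin": self.alpha_bin,
            "alpha_electrode": self.alpha_electrode,
            "kmeans_seed": self.kmeans_seed,
            "classifier_features": list(self.classifier_features),
            "classifier_methods": list(self.classifier_methods),
            "svc_folds": self.svc_folds,
            "spikes_path": self.spikes_path,
            "stims_path": self.stims_path,
            "raw_path": self.raw_path,
        }
        return d


def _section(data: dict, name: str) -> dict:
    value = data.get(name) or {}
    if not isinstance(value, dict):
        raise ValueError(f"config section {name!r} must be a mapping")
    return value


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if overrides:
        data.update(overrides)
    proto = _section(data, "protocol")
    if "site_order" in proto and proto["site_order"] is not None:
        proto["site_order"] = tuple(proto["site_order"])
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        geometry=ArrayGeometry(**_section(data, "geometry")),
        protocol=ProtocolSpec(**proto),
        window=WindowSpec(**_section(data, "window")),
        detection=DetectionParams(**_section(data, "detection")),
        synthetic=_section(data, "synthetic"),
        alpha_bin=float(data.get("alpha_bin", 0.05)),
        alpha_electrode=float(data.get("alpha_electrode", 0.001)),
        kmeans_seed=int(data.get("kmeans_seed", 0)),
        classifier_features=tuple(data.get("classifier_features", ("activation", "tsc", "first_bin"))),
        classifier_methods=tuple(data.get("classifier_methods", ("kmeans", "kmeans_pc", "svc"))),
        svc_folds=int(data.get("svc_folds", 5)),
        spikes_path=data.get("spikes_path"),
        stims_path=data.get("stims_path"),
        raw_path=data.get("raw_path"),
    )
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    canonical = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
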