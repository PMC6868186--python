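"""Pipeline configuration: one YAML-serialisable object with the defaults
the whole toolchain shares (frame geometry, binning, tolerances, training
hyperparameters, seed). Every run can snapshot its effective config and a
stable hash of it for provenance."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    # geometry
    detect_frame_m: int = 15
    detect_frame_n: int = 211
    group_frame_m: int = 15
    group_frame_n: int = 10
    mz_bin_width: float = 0.01
    # clustering / matching tolerances
    cluster_mz_tol: float = 0.01
    match_mz_tol: float = 0.01
    match_rt_tol: float = 0.2
    consensus_ppm_tol: float = 10.0
    consensus_rt_tol: float = 0.03
    # training
    detect_learning_rate: float = 0.01
    group_learning_rate: float = 0.07
    batch_size: int = 128
    patience: int = 5
    max_epochs: int = 100
    val_every: int = 10
    # scanning
    scan_batch_size: int = 256
    anchor_bins: int = 2
    cluster_batch_size: int = 500
    ensemble_size: int = 4
    rng_seed: int = 0
    version: int = CONFIG_VERSION

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if data.get("version", CONFIG_VERSION) != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {data.get('version')}")
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]
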