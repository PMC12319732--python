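"""Run configuration: YAML/JSON loading with strict key validation, manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from framefilter.anneal import CoolingSchedule, OptimizationConfig
from framefilter.synth import SyntheticConfig

__all__ = ["RunConfig", "load_config", "save_config", "RunManifest", "write_manifest"]


@dataclass
class RunConfig:
    """Top-level pipeline configuration with the package defaults filled in."""

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    fraction: float = 0.10
    n_iter: int = 10_000
    alpha: float = 0.01
    n_splits: int = 100
    train_frac: float = 0.8
    null_iters: int = 10_000
    t0: float = 0.05
    texp: float = 0.996
    seed: int = 0

    def optimization_config(self) -> OptimizationConfig:
        return OptimizationConfig(
            n_iter=self.n_iter,
            fraction=self.fraction,
            seed=self.seed,
            cooling=CoolingSchedule(T0=self.t0, Texp=self.texp),
        )


def _build(cls, mapping: dict, path_label: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) in {path_label}: {', '.join(sorted(unknown))}"
        )
    return cls(**mapping)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    synth_raw = raw.pop("synth", {})
    cfg = _build(RunConfig, raw, str(path))
    cfg.synth = _build(SyntheticConfig, synth_raw, f"{path}:synth")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    rec = dataclasses.asdict(cfg)
    tt = rec["synth"]["template_truth"]
    if not isinstance(tt, str):
        rec["synth"]["template_truth"] = [int(v) for v in tt]
    with open(path, "w") as fh:
        yaml.safe_dump(rec, fh, sort_keys=True)


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int
    version: str
    input_digests: dict
    timestamp: str


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(command: str, config: dict, seed: int, inputs: list, out_path) -> RunManifest:
    """Record what ran, with which seeds and inputs, next to the outputs."""
    from framefilter import __version__

    man = RunManifest(
        command=command,
        config=config,
        seed=seed,
        version=__version__,
        input_digests={str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    with open(out_path, "w") as fh:
        json.dump(dataclasses.asdict(man), fh, indent=2)
    return man
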