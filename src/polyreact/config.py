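"""Configuration loading and run manifests.

A run configuration is a YAML file with optional sections ``generator``,
``encoding``, ``embedder``, ``network``, ``train``, ``split`` and
``baseline``; unknown keys are rejected early so typos surface before a long
run.  Every CLI stage writes a :class:`RunManifest` JSON next to its outputs
recording the configuration snapshot, seeds, package version and hashes of
the files it read and wrote.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .classifier import NetworkConfig, TrainConfig
from .descriptors import BaselineConfig
from .embed import MockEmbedder
from .errors import ValidationError
from .evaluate import SplitSpec
from .featurize import EncodingConfig
from .synthetic import GeneratorSpec

_SECTIONS = {
    "generator": GeneratorSpec,
    "encoding": EncodingConfig,
    "network": NetworkConfig,
    "train": TrainConfig,
    "split": SplitSpec,
    "baseline": BaselineConfig,
}


@dataclass
class RunConfig:
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    embedder: dict = field(default_factory=lambda: {"name": "mock", "feature_dim": 32})

    def make_embedder(self):
        name = self.embedder.get("name", "mock")
        if name == "mock":
            return MockEmbedder(
                feature_dim=int(self.embedder.get("feature_dim", 32)),
                special_tokens_per_domain=int(
                    self.embedder.get("special_tokens_per_domain", 2)
                ),
            )
        from .embed import load_external_embedder

        return load_external_embedder(name)

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one master seed into every seeded component."""
        from dataclasses import replace

        return RunConfig(
            generator=replace(self.generator, seed=seed),
            encoding=self.encoding,
            network=replace(self.network, seed=seed),
            train=replace(self.train, seed=seed),
            split=replace(self.split, seed=seed),
            baseline=replace(self.baseline, seed=seed),
            embedder=dict(self.embedder),
        )

    def to_dict(self) -> dict:
        out = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        out["embedder"] = dict(self.embedder)
        return out


def load_config(path=None) -> RunConfig:
    """Load a YAML configuration, falling back to defaults per section."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(raw) - set(_SECTIONS) - {"embedder"}
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        allowed = {f.name for f in fields(cls)}
        bad = set(section) - allowed
        if bad:
            raise ValidationError(f"unknown keys in [{name}]: {sorted(bad)}")
        if name == "generator" and "format_mix" in section:
            section = dict(section)
            section["format_mix"] = dict(section["format_mix"])
        for key in ("concentrations", "coatings", "fractions", "conv_blocks",
                    "head_widths"):
            if key in section and isinstance(section[key], list):
                section = dict(section)
                section[key] = _to_tuple(section[key])
        kwargs[name] = cls(**section)
    kwargs["embedder"] = dict(raw.get("embedder", {"name": "mock", "feature_dim": 32}))
    return RunConfig(**kwargs)


def _to_tuple(x):
    if isinstance(x, list):
        return tuple(_to_tuple(v) for v in x)
    return x


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    stage: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S")
    )

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_sha256(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1),
                              encoding="utf-8")
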