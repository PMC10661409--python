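"""Structured run configuration for the end-to-end pipeline.

A :class:`RunConfig` gathers the synthetic group specifications and all
stage parameters in one YAML-serialisable object, so every default —
band edges, filter range, epoch geometry, entropy parameters, graph
threshold, classifier settings — is visible and overridable in a single
file.  Parsing and serialising round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .complexity import EntropyConfig
from .network import NetworkConfig
from .pipeline import ClassifierConfig
from .preprocess import PreprocessConfig
from .synthetic import GroupSpec, default_specs


@dataclass
class CohortConfig:
    """Synthetic cohort: CN and AD group specifications."""

    cn: GroupSpec = field(default_factory=lambda: default_specs()[0])
    ad: GroupSpec = field(default_factory=lambda: default_specs()[1])

    def validate(self) -> None:
        self.cn.validate()
        self.ad.validate()


@dataclass
class RunConfig:
    """Everything needed for simulate -> preprocess -> extract -> stats ->
    classify, plus the master seed."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    classify: ClassifierConfig = field(default_factory=ClassifierConfig)

    def validate(self) -> None:
        self.cohort.validate()
        self.preprocess.validate()
        self.entropy.validate()
        self.network.validate()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        if "seed" in d:
            cfg.seed = int(d["seed"])
        cohort = d.get("cohort", {})
        for grp in ("cn", "ad"):
            if grp in cohort:
                base = getattr(cfg.cohort, grp)
                setattr(cfg.cohort, grp, _update(base, cohort[grp]))
        for section, attr in (("preprocess", "preprocess"),
                              ("entropy", "entropy"),
                              ("network", "network"),
                              ("classify", "classify")):
            if section in d:
                setattr(cfg, attr, _update(getattr(cfg, attr), d[section]))
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    def digest(self) -> str:
        """Stable hash of the canonical YAML serialisation."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _update(obj, values: dict):
    """Dataclass copy with field overrides; unknown keys are an error."""
    names = {f.name for f in dataclasses.fields(obj)}
    unknown = set(values) - names
    if unknown:
        raise ValueError(
            f"unknown config keys for {type(obj).__name__}: "
            f"{sorted(unknown)}")
    return dataclasses.replace(obj, **values)
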