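"""Run configuration: validated settings for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from wheatgs.evalharness import SCHEME_KINDS
from wheatgs.gsmodels.registry import MODEL_NAMES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated configuration for :func:`wheatgs.study.run_study`.

    Either ``simulate`` (SimConfig fields plus an optional ``traits``
    mapping of per-trait overrides) or ``inputs`` (paths to genotype and
    phenotype files) must be provided.
    """

    seed: int = 0
    output_dir: str = "results/run"
    simulate: dict | None = None
    inputs: dict | None = None
    qc: dict = field(default_factory=dict)
    models: list = field(default_factory=lambda: ["rrblup"])
    model_params: dict = field(default_factory=dict)
    schemes: list = field(default_factory=lambda: [{"kind": "kfcv"}])
    verbosity: str = "INFO"

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be set")
        if self.inputs is not None:
            for key in ("genotypes", "phenotypes"):
                if key not in self.inputs:
                    raise ValueError(f"inputs must name a {key!r} path")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input path does not exist: {self.inputs[key]}")
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(f"unknown model names {unknown}; choose from {MODEL_NAMES}")
        for sch in self.schemes:
            kind = sch.get("kind")
            if kind not in SCHEME_KINDS:
                raise ValueError(f"unknown scheme kind {kind!r}; choose from {SCHEME_KINDS}")
        bad = [m for m in self.model_params if m not in MODEL_NAMES]
        if bad:
            raise ValueError(f"model_params for unknown models {bad}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "output_dir": self.output_dir,
            "simulate": self.simulate, "inputs": self.inputs, "qc": self.qc,
            "models": list(self.models), "model_params": self.model_params,
            "schemes": list(self.schemes), "verbosity": self.verbosity,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
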