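"""Pipeline configuration: a flat YAML-backed set of tunables.

Unknown keys are rejected so a typo cannot silently fall back to defaults;
the effective configuration is echoed into every output directory.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class PipelineConfig:
    # tissue mask
    tolerance: float = 0.12
    seed_policy: str = "border"
    # white regions
    gamma: float = 6.0
    min_area: int = 60
    max_area: int | None = None
    connectivity: int = 8
    # Gabor banks
    lambda_min: float = 4.0
    sigma_rule: float = 0.56
    psi: float = 0.0
    # classifier
    C: float = 1.0
    folds: int = 10
    # micro subsampling
    rate_micro: float = 0.0002
    rate_other: float = 0.00001
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(os.fspath(path)) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def with_overrides(self, **kw) -> "PipelineConfig":
        known = {f.name for f in fields(self)}
        bad = set(kw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        doc = asdict(self)
        doc.update({k: v for k, v in kw.items() if v is not None})
        return PipelineConfig(**doc)

    def echo(self, outdir: str | os.PathLike) -> None:
        os.makedirs(os.fspath(outdir), exist_ok=True)
        with open(os.path.join(os.fspath(outdir), "config.json"), "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
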