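"""Layered pipeline configuration: defaults < YAML file < explicit overrides.

Every report embeds ``config_hash()`` so results are traceable to the
exact tolerances and rule parameters that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from ..composition import CompositionConstraints
from ..errors import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    """All tolerances and decision parameters for the elucidation pipeline.

    ``tol_ppm`` is the precursor exact-mass tolerance (instrument-level
    accuracy); ``fragment_tol_mz`` is the unit-resolution product-ion
    match window used for both CID and OzID. ``sn2_ratio`` is the
    decision threshold for calling an acyl sn-2 (its mean relative loss
    abundance must fall below ``sn2_ratio`` times the minimum of the
    others'). Geometry reference ratios are aldehyde:Criegee priors per
    geometry; they are calibration data, not instrument constants.
    """

    tol_ppm: float = 20.0
    fragment_tol_mz: float = 0.3
    sn2_ratio: float = 0.5
    geometry_references: dict[str, float] = field(
        default_factory=lambda: {"cis": 2.0, "trans": 8.0}
    )
    geometry_rel_tol: float = 0.5
    constraints: CompositionConstraints = field(default_factory=CompositionConstraints)

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0 or self.fragment_tol_mz <= 0:
            raise ConfigError("tolerances must be positive")
        if not 0 < self.sn2_ratio <= 1:
            raise ConfigError("sn2_ratio must be in (0, 1]")
        if self.geometry_rel_tol <= 0:
            raise ConfigError("geometry_rel_tol must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping, then apply keyword overrides on top."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        merged = {**raw, **overrides}
        return cls.build(**merged)

    @classmethod
    def build(cls, **kwargs) -> "PipelineConfig":
        if "constraints" in kwargs and isinstance(kwargs["constraints"], dict):
            raw = dict(kwargs["constraints"])
            for key in ("long_carbons", "long_db", "short_carbons", "short_db"):
                if key in raw:
                    raw[key] = tuple(raw[key])
            kwargs["constraints"] = CompositionConstraints(**raw)
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return replace(self, **overrides)
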