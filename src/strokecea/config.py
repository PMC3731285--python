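"""Run configuration: schema, loading, seed fan-out and run manifests.

The YAML/JSON config is validated by pydantic before any computation.
Every default that stands in for an unpublished supplementary value is
marked ``assumption: true`` in the JSON schema so consumers can tell
calibrated inputs from published ones.

A single top-level seed fans out to named sub-streams (one per register,
one for the PSA) so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config", "subseed", "write_manifest", "config_hash"]


def _assumption(**kwargs):
    return Field(json_schema_extra={"assumption": True}, **kwargs)


class AdjustmentConfig(BaseModel):
    mortality_pp_at_30d: float = Field(default=2.4, ge=0)
    su_los_reduction_days: float = Field(default=5.0, ge=0)
    adjust_mortality: bool = True
    adjust_los: bool = True
    mortality_mode: str = "rescale"

    @field_validator("mortality_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("rescale", "day30"):
            raise ValueError("mortality_mode must be 'rescale' or 'day30'")
        return v


class UtilityConfig(BaseModel):
    slope: float = _assumption(default=0.05, ge=0)
    intercept: float = _assumption(default=-0.235)


class PSAConfig(BaseModel):
    n_draws: int = Field(default=10_000, ge=2)
    cost_cv: float = _assumption(default=0.20, ge=0)
    long_run_concentration: float = _assumption(default=200.0, gt=0)


class GeneratorOverrides(BaseModel):
    n_before: int | None = Field(default=None, ge=1)
    n_after: int | None = Field(default=None, ge=1)
    n_after_alt: int | None = Field(default=None, ge=1)
    censor_day: int = Field(default=365, ge=90)


class RunConfig(BaseModel):
    """Top-level run configuration (all fields have working defaults)."""

    seed: int = 0
    output_dir: Path = Path("outputs")
    cohort_size: int = Field(default=6438, ge=1)
    register_before: Path = Path("register_before.csv")
    register_after: Path = Path("register_after.csv")
    register_after_alt: Path | None = Path("register_after_nl_slsr.csv")
    generator: GeneratorOverrides = GeneratorOverrides()
    adjustments: AdjustmentConfig = AdjustmentConfig()
    discount_rate: float = Field(default=0.035, ge=0)
    utility: UtilityConfig = UtilityConfig()
    psa: PSAConfig = PSAConfig()
    inpatient_rule: str = "institutional"
    scenarios: list[str] | None = None
    perspective: str = "NHS+PSS"

    @field_validator("inpatient_rule")
    @classmethod
    def _rule(cls, v: str) -> str:
        if v not in ("institutional", "home"):
            raise ValueError("inpatient_rule must be 'institutional' or 'home'")
        return v

    @field_validator("perspective")
    @classmethod
    def _perspective(cls, v: str) -> str:
        if v not in ("NHS+PSS", "NHS-only"):
            raise ValueError("perspective must be 'NHS+PSS' or 'NHS-only'")
        return v


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML/JSON config; None yields the defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    data.update(overrides)
    return RunConfig.model_validate(data)


def subseed(seed: int, stream: str) -> int:
    """Deterministic sub-seed (< 2^31) for a named random stream."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stream.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir: Path, command: str) -> Path:
    """Write the reproducibility manifest next to a command's outputs."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("strokecea")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "command": command,
        "seed": config.seed,
        "config_sha256": config_hash(config),
        "package_version": pkg_version,
        "config": config.model_dump(mode="json"),
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return path
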