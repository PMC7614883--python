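"""Configuration loading/validation and output serialization.

Run configurations are YAML files validated against a strict schema
(unknown keys rejected, every violation reported, applied defaults
logged).  Outputs are plain delimited tables plus a JSON manifest with
checksums, so that a config + master seed reproduces every output file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import ti, tic
from .population import PopulationConfig

logger = logging.getLogger("ticsim")

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "write_outputs"]


class ConfigError(ValueError):
    """Raised with every schema violation enumerated, not just the first."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class TIParamsModel(_Strict):
    V: float = Field(1.5, gt=0)
    k1: float = Field(1.0, gt=0)
    k2: float = Field(1.0, gt=0)
    k3: float = Field(1.0, gt=0)
    n: float = Field(2.0, gt=1)
    psi: float = Field(1.0, gt=0)
    gamma1: float = Field(0.1, gt=0)
    gamma2: float = Field(0.1, gt=0)
    sigma1: float = Field(0.05, ge=0)
    sigma2: float = Field(0.05, ge=0)


class TriggerModel(_Strict):
    kind: Literal["none", "constant", "pulse", "stochastic"] = "none"
    amplitude: float = Field(1.0, ge=0)
    t_on: float = Field(0.0, ge=0)
    duration: float = Field(72.0, gt=0)
    probability: float = Field(0.0, ge=0, le=1)


class IntegrationModel(_Strict):
    dt: float = Field(ti.DEFAULT_DT, gt=0)
    generation_hours: float = Field(ti.DEFAULT_GENERATION_HOURS, gt=0)
    t_end: float = Field(720.0, gt=0)
    s_silenced: float = Field(ti.DEFAULT_S_SILENCED, gt=0)


class PopulationModel(_Strict):
    n_worms: int = Field(250, ge=1)
    selection_mode: Literal["random", "directed"] = "random"
    s_select: float = Field(3.0, gt=0)
    n_generations: int = Field(20, ge=1)
    init_g: float = Field(3.0, ge=0)
    init_h: float = Field(0.0, ge=0)


class TICModel(_Strict):
    V_tot: float = Field(300.0, gt=0)
    N: int | None = Field(None, ge=1)
    q: float | None = Field(None, ge=0, le=1)
    lam: float | None = Field(10.0, ge=0)
    injection_g: float = Field(3.0, ge=0)
    injection_h: float = Field(0.0, ge=0)
    c_min: float | None = Field(None, gt=0)
    n_generations: int = Field(300, ge=1)
    burn_in_frac: float = Field(0.2, ge=0, lt=1)
    initial_pool: int = Field(0, ge=0)
    sigma: float = Field(tic.TIC_SIGMA, ge=0)


class NormalFormModel(_Strict):
    mu: float = 0.0
    sigma: float = Field(0.1, ge=0)
    x0: float = -3.0
    xmax: float = 10.0
    gamma: float = Field(1.0, gt=0)
    n_paths: int = Field(100, ge=1)
    dt: float = Field(0.01, gt=0)


class RunConfig(_Strict):
    """Top-level experiment configuration."""

    kind: Literal["simulate-ti", "population", "tic", "normal-form"] = "simulate-ti"
    seed: int = 0
    out_dir: str = "runs/out"
    integration: IntegrationModel = Field(default_factory=IntegrationModel)
    ti: TIParamsModel = Field(default_factory=TIParamsModel)
    trigger: TriggerModel = Field(default_factory=TriggerModel)
    population: PopulationModel = Field(default_factory=PopulationModel)
    tic: TICModel = Field(default_factory=TICModel)
    normal_form: NormalFormModel = Field(default_factory=NormalFormModel)

    # ---- converters to the runtime dataclasses ----

    def ti_params(self) -> ti.TIParams:
        return ti.TIParams(**self.ti.model_dump())

    def trigger_schedule(self, rng=None) -> ti.TriggerSchedule:
        t = self.trigger
        if t.kind == "none":
            return ti.TriggerSchedule.none()
        if t.kind == "constant":
            return ti.TriggerSchedule.constant(t.amplitude)
        if t.kind == "pulse":
            return ti.TriggerSchedule.pulse(t.amplitude, t.t_on, t.duration)
        import numpy as np

        return ti.TriggerSchedule.stochastic(
            t.amplitude,
            t.probability,
            self.integration.t_end,
            rng if rng is not None else np.random.default_rng(self.seed),
            self.integration.generation_hours,
        )

    def population_config(self) -> PopulationConfig:
        p = self.population
        return PopulationConfig(
            n_worms=p.n_worms,
            selection_mode=p.selection_mode,
            s_select=p.s_select,
            s_silenced=self.integration.s_silenced,
            generation_hours=self.integration.generation_hours,
            n_generations=p.n_generations,
            dt=self.integration.dt,
            seed=self.seed,
        )

    def tic_config(self) -> tic.TICConfig:
        t = self.tic
        base = ti.TIParams(**{**self.ti.model_dump(), "sigma1": t.sigma, "sigma2": t.sigma})
        return tic.TICConfig(
            V_tot=t.V_tot,
            N=t.N,
            q=t.q,
            lam=t.lam,
            injection_g=t.injection_g,
            injection_h=t.injection_h,
            c_min=t.c_min,
            s_silenced=self.integration.s_silenced,
            ti=base,
            dt=self.integration.dt,
            generation_hours=self.integration.generation_hours,
        )


def _log_defaults(model: BaseModel, provided: Any, prefix: str = "") -> None:
    if not isinstance(provided, dict):
        provided = {}
    for name in type(model).model_fields:
        val = getattr(model, name)
        if name not in provided:
            if isinstance(val, BaseModel):
                _log_defaults(val, {}, prefix=f"{prefix}{name}.")
            else:
                logger.info("config default applied: %s%s = %r", prefix, name, val)
        elif isinstance(val, BaseModel):
            _log_defaults(val, provided.get(name), prefix=f"{prefix}{name}.")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected; all schema violations are reported
    together; every field filled from a default is logged."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError(
            f"{path}: {len(msgs)} validation error(s):\n  " + "\n  ".join(msgs)
        ) from exc
    _log_defaults(cfg, raw)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))


def _package_version() -> str:
    try:
        return version("ticsim")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    tables: dict[str, pd.DataFrame],
    manifest: dict,
    out_dir: str | Path,
    float_format: str = "%.10g",
) -> dict:
    """Write delimited tables plus a JSON manifest with checksums.

    Each table lands as ``<name>.tsv`` (tab-separated, no index; empty
    tables produce a header-only file).  Writes go through a temporary
    file and an atomic rename; an interrupted write leaves a
    ``<name>.tsv.partial`` marker rather than a truncated table.  The
    manifest echoes the caller-supplied metadata and inventories every
    file with its SHA-256.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, dict] = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        marker = out / f"{name}.tsv.partial"
        tmp = out / f".{name}.tsv.tmp"
        marker.touch()
        try:
            df.to_csv(tmp, sep="\t", index=False, float_format=float_format)
            os.replace(tmp, path)
        finally:
            if tmp.exists():  # pragma: no cover - failure path
                tmp.unlink()
            else:
                marker.unlink()
        inventory[name] = {
            "path": path.name,
            "sha256": _sha256(path),
            "n_rows": int(len(df)),
        }
    full = {
        "package_version": _package_version(),
        **manifest,
        "files": inventory,
    }
    tmp = out / ".manifest.json.tmp"
    tmp.write_text(json.dumps(full, indent=2, sort_keys=True, default=str) + "\n")
    os.replace(tmp, out / "manifest.json")
    return inventory
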