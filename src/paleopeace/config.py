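"""Declarative pipeline configuration (TOML) with validation."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .forest import ModelConfig
from .synthetic import GridExtent, TraumaCoefficients, WorldConfig


class ValidationError(ValueError):
    """Configuration fails validation before any compute starts."""


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: bool = True
    # input paths, used when simulate is False
    curve_path: str | None = None  # None -> bundled reference curve
    marine_curve_path: str | None = None
    individuals_path: str | None = None
    dates_path: str | None = None
    climate_path: str | None = None
    sst_paths: list[str] = field(default_factory=list)
    enso_path: str | None = None
    # stage settings
    world: WorldConfig = field(default_factory=WorldConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    n_draws: int = 1000
    radius_km: float = 20.0
    kde_replicates: int = 1000
    kde_bandwidth: float = 50.0
    max_date_error: float = 100.0
    bin_cutoff: float = 200.0
    taphonomic_correction: bool = False
    save_inputs: bool = True  # write the simulated world's CSVs to out_dir/data
    regions: tuple[str, ...] = ("coast", "inland")

    def validate(self) -> None:
        if self.model.n_models > self.n_draws:
            raise ValidationError(
                f"n_models={self.model.n_models} exceeds n_draws={self.n_draws}"
            )
        if self.n_draws < 1 or self.kde_replicates < 1:
            raise ValidationError("n_draws and kde_replicates must be >= 1")
        if self.radius_km <= 0:
            raise ValidationError("radius_km must be > 0")
        for r in self.regions:
            if r not in ("coast", "inland"):
                raise ValidationError(f"unknown region {r!r}")
        if self.simulate:
            self.world.validate()
        else:
            for label, p in (
                ("individuals_path", self.individuals_path),
                ("dates_path", self.dates_path),
                ("climate_path", self.climate_path),
                ("enso_path", self.enso_path),
            ):
                if p is None:
                    raise ValidationError(f"{label} is required when simulate=false")
                if not Path(p).exists():
                    raise ValidationError(f"{label}: {p} does not exist")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pop_section(raw: dict, key: str) -> dict:
    sec = raw.pop(key, {}) or {}
    if not isinstance(sec, dict):
        raise ValidationError(f"[{key}] must be a table")
    return sec


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML pipeline configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    world_raw = _pop_section(raw, "world")
    model_raw = _pop_section(raw, "model")
    extent_raw = world_raw.pop("grid_extent", None)
    coeff_raw = world_raw.pop("trauma_coefficients", None)
    world_kwargs = dict(world_raw)
    if "time_span" in world_kwargs:
        world_kwargs["time_span"] = tuple(world_kwargs["time_span"])
    if extent_raw is not None:
        world_kwargs["grid_extent"] = GridExtent(**extent_raw)
    if coeff_raw is not None:
        inter = coeff_raw.pop("interaction", None)
        world_kwargs["trauma_coefficients"] = TraumaCoefficients(
            interaction=tuple(inter) if inter else None, **coeff_raw
        )
    try:
        world = WorldConfig(**world_kwargs)
        model = ModelConfig(**model_raw)
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        cfg = PipelineConfig(world=world, model=model, **raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(str(exc)) from exc
    return cfg
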