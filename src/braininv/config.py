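"""TOML run configuration with strict schema validation.

A run config describes one study: model, connectome source or synthesis,
simulation grid, feature recipe, inference settings, and output paths.
Unknown keys are rejected (misspellings fail loudly, naming the field), every
stochastic stage has an explicit seed, and the fully resolved config records
which values were user-supplied and which came from defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

from .errors import ValidationError

__all__ = ["RunConfig", "validate_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    id: str
    overrides: dict = {}


class ConnectomeSection(_Strict):
    path: str | None = None
    format: str | None = None
    n_regions: int = 20
    density: float = 0.6
    seed: int = 0


class SimulationSection(_Strict):
    dt: float = 1e-4
    duration: float = 2.2
    transient_fraction: float = 0.1
    record_every: int = 1
    seed: int = 0


class FeatureSection(_Strict):
    recipe: dict = {}


class InferenceSection(_Strict):
    family: str = "MAF"
    budget: int = 1000
    batch_size: int = 256
    learning_rate: float = 5e-4
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0
    n_draws: int = 10_000


class OutputSection(_Strict):
    directory: str = "braininv_out"
    format: str = "hdf5"


class RunConfig(_Strict):
    model: ModelSection
    connectome: ConnectomeSection = ConnectomeSection()
    simulation: SimulationSection = SimulationSection()
    features: FeatureSection = FeatureSection()
    inference: InferenceSection = InferenceSection()
    output: OutputSection = OutputSection()
    theta_true: list[float] | None = None
    prior_lower: list[float] | None = None
    prior_upper: list[float] | None = None

    def provenance(self, raw: dict) -> dict:
        """Record, per section, which keys were user-set vs defaulted."""
        out = {}
        for section in ("model", "connectome", "simulation", "features",
                        "inference", "output"):
            given = set(raw.get(section, {}))
            resolved = getattr(self, section).model_dump()
            out[section] = {
                k: ("user" if k in given else "default") for k in resolved
            }
        return out


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML config, raising on any schema violation."""
    raw = tomllib.loads(Path(path).read_text())
    try:
        cfg = RunConfig(**raw)
    except PydanticValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValidationError(f"invalid config field '{loc}': {first['msg']}") from exc
    if cfg.theta_true is not None and cfg.prior_lower and cfg.prior_upper:
        inside = all(lo <= t <= hi for t, lo, hi in
                     zip(cfg.theta_true, cfg.prior_lower, cfg.prior_upper))
        if not inside:
            raise ValidationError("theta_true lies outside the prior box")
    return cfg
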