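"""Shared simulator contract: results container, noise streams, Heun stepping.

All six network models integrate Itô SDEs with a stochastic Heun scheme
(deterministic Heun when sigma = 0): a Euler predictor including the noise
increment, then a trapezoidal corrector reusing the same increment. Noise is
pre-generated per region from independent Philox substreams spawned from the
master seed, so that with zero coupling each region's trajectory is
bit-identical to an isolated single-node run driven by that region's stream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from ..errors import DivergenceError, PreconditionError

__all__ = ["SimulationResult", "noise_streams", "params_digest", "check_finite"]


@dataclass
class SimulationResult:
    """Regional time series from one model run.

    ``states`` holds the model's observable (E, y1-y2, Re[Z], x, r, or S) as
    an (N, T) array on the strictly increasing grid ``time``; additional state
    variables live in ``extras``. ``dt`` is the recording step in ``time_unit``.
    """

    time: np.ndarray
    states: np.ndarray
    dt: float
    model_id: str
    seed: int
    params_digest: str
    time_unit: str = "s"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.states.ndim != 2 or self.states.shape[1] != self.time.shape[0]:
            raise PreconditionError(
                f"states shape {self.states.shape} inconsistent with "
                f"time length {self.time.shape[0]}"
            )
        if np.any(np.diff(self.time) <= 0):
            raise PreconditionError("time grid must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return self.states.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0] + self.dt)


def params_digest(params) -> str:
    """Stable short digest of a parameter set (for provenance tracking)."""
    return hashlib.md5(repr(params).encode()).hexdigest()[:12]


def noise_streams(
    seed: int,
    n_regions: int,
    n_steps: int,
    n_channels: int = 1,
    n_init: int = 0,
    region_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region standard-normal streams for initial conditions and noise.

    Returns ``(noise, init)`` with shapes (n_channels, n_steps, n_regions) and
    (n_init, n_regions). Region k's numbers come from the Philox substream
    with spawn key ``region_offset + k`` of the master seed: streams are
    independent across regions and do not depend on how many regions are
    simulated together, so an isolated run of region k (``region_offset=k``,
    one region) consumes bit-identical numbers to region k of a network run.
    """
    out = np.empty((n_channels, n_steps, n_regions))
    init = np.empty((n_init, n_regions))
    for k in range(n_regions):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(region_offset + k,))
        rng = np.random.Generator(np.random.Philox(child))
        if n_init:
            init[:, k] = rng.standard_normal(n_init)
        out[:, :, k] = rng.standard_normal((n_channels, n_steps))
    return out, init


def check_finite(states: np.ndarray, model_id: str, fail_step: int = -1) -> None:
    """Raise DivergenceError naming the first bad step, if any."""
    if fail_step >= 0:
        raise DivergenceError(
            f"{model_id}: non-finite state at integration step {fail_step}",
            step=fail_step,
        )
    if not np.all(np.isfinite(states)):
        bad = np.argwhere(~np.isfinite(states))
        raise DivergenceError(
            f"{model_id}: non-finite value in recorded states at index {tuple(bad[0])}"
        )
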