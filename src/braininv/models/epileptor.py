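"""2-D Epileptor network model of epilepsy spread.

Fast-slow dynamics per region: a fast variable x on a cubic nullcline and a
slow recovery variable z relaxing on timescale tau. The spatial map of
epileptogenicity eta_i sets each region's distance from the seizure
bifurcation: high (less negative) eta yields autonomous seizure oscillations,
values near the bifurcation seize only when recruited through the connectome
(the coupling enters the slow equation), and low eta regions stay at a stable
equilibrium. The model is deterministic; observation noise, when wanted, is a
feature-stage concern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ..connectome import StructuralConnectome
from ..errors import PreconditionError
from .base import SimulationResult, check_finite, noise_streams, params_digest

__all__ = ["EpileptorParams", "simulate_epileptor2d"]


@dataclass
class EpileptorParams:
    """2-D Epileptor parameters; tau in ms, eta per region (broadcastable)."""

    I: float = 3.1
    tau: float = 90.0
    eta: np.ndarray | float = -3.65
    G: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise PreconditionError("tau must be positive")

    def eta_vector(self, n: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.eta, dtype=float), (n,)).copy()


@njit(cache=True)
def _epi_core(W, I, tau, eta, G, dt, n_steps, rec_every, x0, z0):
    n = W.shape[0]
    n_rec = n_steps // rec_every
    x_rec = np.empty((n, n_rec))
    z_rec = np.empty((n, n_rec))
    x = x0.copy()
    z = z0.copy()
    dx1 = np.empty(n)
    dz1 = np.empty(n)
    dx2 = np.empty(n)
    dz2 = np.empty(n)
    xp = np.empty(n)
    zp = np.empty(n)
    fail = -1
    j = 0
    for step in range(n_steps):
        for i in range(n):
            coup = 0.0
            if G != 0.0:
                for k in range(n):
                    coup += W[i, k] * (x[k] - x[i])
            dx1[i] = 1.0 - x[i] ** 3 - 2.0 * x[i] ** 2 - z[i] + I
            dz1[i] = (4.0 * (x[i] - eta[i]) - z[i] - G * coup) / tau
        for i in range(n):
            xp[i] = x[i] + dt * dx1[i]
            zp[i] = z[i] + dt * dz1[i]
        for i in range(n):
            coup = 0.0
            if G != 0.0:
                for k in range(n):
                    coup += W[i, k] * (xp[k] - xp[i])
            dx2[i] = 1.0 - xp[i] ** 3 - 2.0 * xp[i] ** 2 - zp[i] + I
            dz2[i] = (4.0 * (xp[i] - eta[i]) - zp[i] - G * coup) / tau
        for i in range(n):
            x[i] += 0.5 * dt * (dx1[i] + dx2[i])
            z[i] += 0.5 * dt * (dz1[i] + dz2[i])
        if (step + 1) % rec_every == 0:
            ok = True
            for i in range(n):
                x_rec[i, j] = x[i]
                z_rec[i, j] = z[i]
                if not np.isfinite(x[i]):
                    ok = False
            if not ok:
                fail = step
                break
            j += 1
    return x_rec, z_rec, fail


def simulate_epileptor2d(
    sc: StructuralConnectome,
    params: EpileptorParams,
    duration: float,
    dt: float = 0.05,
    seed: int = 0,
    record_every: int = 1,
    x0: np.ndarray | float | None = None,
    z0: np.ndarray | float | None = None,
    init_scale: float = 0.01,
) -> SimulationResult:
    """Integrate the 2-D Epileptor network; observable is x (z in extras).

    Default initial conditions sit near the healthy equilibrium
    (x = -2.5, z = 4.0) with small per-region perturbations from the seed
    stream; pass ``x0``/``z0`` to override (scalar or length-N).
    """
    if not sc.normalized:
        raise PreconditionError("connectome must be normalized before simulation")
    n = sc.n_regions
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise PreconditionError("duration shorter than one step")
    eta = params.eta_vector(n)
    _, init = noise_streams(seed, n, 1, n_channels=1, n_init=2)
    xi = (np.full(n, -2.5) + init[0] * init_scale if x0 is None
          else np.broadcast_to(np.asarray(x0, dtype=float), (n,)).copy())
    zi = (np.full(n, 4.0) + init[1] * init_scale if z0 is None
          else np.broadcast_to(np.asarray(z0, dtype=float), (n,)).copy())
    x_rec, z_rec, fail = _epi_core(
        sc.weights, params.I, params.tau, eta, params.G, dt, n_steps,
        record_every, xi, zi,
    )
    check_finite(x_rec, "epileptor2d", fail)
    rec_dt = dt * record_every
    time = rec_dt * np.arange(1, x_rec.shape[1] + 1)
    return SimulationResult(
        time=time, states=x_rec, dt=rec_dt, model_id="epileptor2d",
        seed=seed, params_digest=params_digest(params), time_unit="ms",
        extras={"z": z_rec},
    )
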