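"""Network of Stuart-Landau oscillators with conduction delays.

Each region is a complex normal-form Hopf oscillator Z_j; for bifurcation
parameter a < 0 it shows damped oscillations at its natural angular frequency
omega_j (default 2*pi*40 rad/s), sustained by noise. Regions couple
diffusively through the connectome with pairwise discrete delays
T_jk = d_jk / v (rounded to the nearest integration step). Observable: Re[Z].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ..connectome import StructuralConnectome, delay_matrix
from ..errors import ConfigurationError, PreconditionError
from .base import SimulationResult, check_finite, noise_streams, params_digest

__all__ = ["StuartLandauParams", "simulate_stuart_landau"]


@dataclass
class StuartLandauParams:
    """Stuart-Landau network parameters (time in seconds).

    ``omega`` may be a scalar (shared natural frequency) or a length-N vector
    of angular frequencies in rad/s. ``velocity`` is the average conduction
    velocity in m/s used to convert distances into delays.
    """

    a: float = -5.0
    omega: np.ndarray | float = 2 * np.pi * 40.0
    G: float = 350.0
    velocity: float = 6.0
    sigma: float = 1e-4

    def __post_init__(self):
        if self.sigma < 0:
            raise PreconditionError("sigma must be non-negative")
        if self.velocity <= 0:
            raise PreconditionError("velocity must be positive")

    def omega_vector(self, n: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.omega, dtype=float), (n,)).copy()


@njit(cache=True)
def _sl_core(W, D, a, omega, G, sigma, dt, n_steps, rec_every, noise, x0, y0, L):
    n = W.shape[0]
    n_rec = n_steps // rec_every
    out = np.empty((n, n_rec))
    xh = np.empty((L, n))
    yh = np.empty((L, n))
    for b in range(L):  # history: initial state held constant on [-max T, 0]
        for k in range(n):
            xh[b, k] = x0[k]
            yh[b, k] = y0[k]
    x = x0.copy()
    y = y0.copy()
    xp = np.empty(n)
    yp = np.empty(n)
    dx1 = np.empty(n)
    dy1 = np.empty(n)
    dx2 = np.empty(n)
    dy2 = np.empty(n)
    sqdt = np.sqrt(dt)
    fail = -1
    j = 0
    for step in range(n_steps):
        for i in range(n):
            amp2 = x[i] * x[i] + y[i] * y[i]
            cx = 0.0
            cy = 0.0
            if G != 0.0:
                for k in range(n):
                    w = W[i, k]
                    if w != 0.0:
                        b = (step - D[i, k]) % L
                        cx += w * (xh[b, k] - x[i])
                        cy += w * (yh[b, k] - y[i])
            dx1[i] = x[i] * (a - amp2) - omega[i] * y[i] + G * cx
            dy1[i] = y[i] * (a - amp2) + omega[i] * x[i] + G * cy
        for i in range(n):
            xp[i] = x[i] + dt * dx1[i] + sigma * sqdt * noise[0, step, i]
            yp[i] = y[i] + dt * dy1[i] + sigma * sqdt * noise[1, step, i]
        for i in range(n):
            amp2 = xp[i] * xp[i] + yp[i] * yp[i]
            cx = 0.0
            cy = 0.0
            if G != 0.0:
                for k in range(n):
                    w = W[i, k]
                    if w != 0.0:
                        b = (step + 1 - D[i, k]) % L
                        cx += w * (xh[b, k] - xp[i])
                        cy += w * (yh[b, k] - yp[i])
            dx2[i] = xp[i] * (a - amp2) - omega[i] * yp[i] + G * cx
            dy2[i] = yp[i] * (a - amp2) + omega[i] * xp[i] + G * cy
        for i in range(n):
            x[i] += 0.5 * dt * (dx1[i] + dx2[i]) + sigma * sqdt * noise[0, step, i]
            y[i] += 0.5 * dt * (dy1[i] + dy2[i]) + sigma * sqdt * noise[1, step, i]
        b = (step + 1) % L
        for i in range(n):
            xh[b, i] = x[i]
            yh[b, i] = y[i]
        if (step + 1) % rec_every == 0:
            ok = True
            for i in range(n):
                out[i, j] = x[i]
                if not np.isfinite(x[i]):
                    ok = False
            if not ok:
                fail = step
                break
            j += 1
    return out, fail


def simulate_stuart_landau(
    sc: StructuralConnectome,
    params: StuartLandauParams,
    duration: float,
    dt: float = 1e-4,
    seed: int = 0,
    record_every: int = 1,
    z0: complex | np.ndarray | None = None,
    init_scale: float = 0.01,
    region_offset: int = 0,
) -> SimulationResult:
    """Integrate the delayed Stuart-Landau network; observable is Re[Z].

    Delays are ``distances / velocity`` rounded to the nearest step; an edge
    whose positive delay rounds below one step is unresolvable at this dt and
    raises ConfigurationError. History is the initial state held constant.
    ``z0`` overrides the default random initial condition (complex scalar or
    length-N complex array).
    """
    if not sc.normalized:
        raise PreconditionError("connectome must be normalized before simulation")
    n = sc.n_regions
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise PreconditionError("duration shorter than one step")
    omega = params.omega_vector(n)

    if params.G != 0.0:
        if sc.distances is None:
            raise PreconditionError("delayed coupling requires a distance matrix")
        T = delay_matrix(sc, params.velocity)
        edges = (sc.weights > 0) & (T > 0)
        if np.any((sc.weights > 0) & (T > 0) & (T < dt)):
            raise ConfigurationError(
                f"dt={dt} exceeds the smallest positive delay "
                f"{T[edges].min():.2e} s; delays unresolvable"
            )
        D = np.rint(T / dt).astype(np.int64)
        if np.any((sc.weights > 0) & (D == 0) & (T > 0)):
            raise ConfigurationError("some positive delays round to zero steps")
    else:
        D = np.zeros((n, n), dtype=np.int64)
    L = int(D.max()) + 2

    noise, init = noise_streams(seed, n, n_steps, n_channels=2, n_init=2,
                                region_offset=region_offset)
    if z0 is None:
        x0 = init[0] * init_scale
        y0 = init[1] * init_scale
    else:
        z = np.broadcast_to(np.asarray(z0, dtype=complex), (n,))
        x0 = z.real.copy()
        y0 = z.imag.copy()
    out, fail = _sl_core(
        sc.weights, D, params.a, omega, params.G, params.sigma, dt, n_steps,
        record_every, noise, x0, y0, L,
    )
    check_finite(out, "stuart_landau", fail)
    rec_dt = dt * record_every
    time = rec_dt * np.arange(1, out.shape[1] + 1)
    return SimulationResult(
        time=time, states=out, dt=rec_dt, model_id="stuart_landau",
        seed=seed, params_digest=params_digest(params), time_unit="s",
    )
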