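"""Jansen-Rit three-population neural-mass network (EEG/MEG-like signals).

Six states per region: membrane potentials of pyramidal cells (y0), excitatory
(y1) and inhibitory (y2) interneuron inputs, plus their derivatives (y3-y5).
The regional output is y1 - y2; regions couple through the firing rate
S(y1 - y2) weighted by the normalized connectome and scaled by G. The
external pyramidal drive P(t) is a constant mean plus Gaussian increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ..connectome import StructuralConnectome
from ..errors import PreconditionError
from .base import SimulationResult, check_finite, noise_streams, params_digest

__all__ = ["JansenRitParams", "jr_sigmoid", "simulate_jansen_rit"]


@dataclass
class JansenRitParams:
    """Jansen-Rit parameters; time in seconds, potentials in mV, rates in Hz.

    ``C`` is the per-region base synapse count; the four connectivity
    constants derive from it as (C1, C2, C3, C4) = (C, 0.8C, 0.25C, 0.25C).
    ``P`` is the mean pulse density of the external drive (Hz); the classic
    single-column model drives it with fluctuating input in the 120-320 Hz
    range, so the default mean is the midpoint 220. ``sigma`` is the SD of
    the white-noise drive increments; the default keeps the stochastic
    spectral peak inside the deterministic limit cycle's alpha band.
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    v_max: float = 5.0
    v0: float = 6.0
    r: float = 0.56
    C: np.ndarray | float = 135.0
    G: float = 1.5
    P: float = 220.0
    sigma: float = 5.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise PreconditionError("PSP rate constants a, b must be positive")
        if self.v_max <= 0:
            raise PreconditionError("v_max must be positive")
        if np.any(np.asarray(self.C) <= 0):
            raise PreconditionError("C must be positive")

    def c_vector(self, n: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.C, dtype=float), (n,)).copy()


def jr_sigmoid(v, params: JansenRitParams):
    """Potential-to-rate sigmoid S(v) = v_max / (1 + exp(r (v0 - v)))."""
    return params.v_max / (1.0 + np.exp(params.r * (params.v0 - np.asarray(v, dtype=float))))


@njit(cache=True)
def _jr_core(W, A, B, a, b, vmax, v0, r, C, G, P, sigma, dt, n_steps,
             rec_every, noise, y_init):
    n = W.shape[0]
    n_rec = n_steps // rec_every
    out = np.empty((n, n_rec))
    y = y_init.copy()  # (6, n)
    d1 = np.empty((6, n))
    d2 = np.empty((6, n))
    yp = np.empty((6, n))
    S_net = np.empty(n)
    sqdt = np.sqrt(dt)
    fail = -1
    j = 0
    for step in range(n_steps):
        for st in range(2):
            src = y if st == 0 else yp
            dd = d1 if st == 0 else d2
            for i in range(n):
                S_net[i] = vmax / (1.0 + np.exp(r * (v0 - (src[1, i] - src[2, i]))))
            for i in range(n):
                H = 0.0
                if G != 0.0:
                    for k in range(n):
                        H += W[i, k] * S_net[k]
                c1 = C[i]
                c2 = 0.8 * C[i]
                c3 = 0.25 * C[i]
                c4 = 0.25 * C[i]
                s_py = vmax / (1.0 + np.exp(r * (v0 - (src[1, i] - src[2, i]))))
                s_e = vmax / (1.0 + np.exp(r * (v0 - c1 * src[0, i])))
                s_i = vmax / (1.0 + np.exp(r * (v0 - c3 * src[0, i])))
                dd[0, i] = src[3, i]
                dd[1, i] = src[4, i]
                dd[2, i] = src[5, i]
                dd[3, i] = A * a * s_py - 2.0 * a * src[3, i] - a * a * src[0, i]
                dd[4, i] = (A * a * (P + c2 * s_e + G * H)
                            - 2.0 * a * src[4, i] - a * a * src[1, i])
                dd[5, i] = B * b * (c4 * s_i) - 2.0 * b * src[5, i] - b * b * src[2, i]
            if st == 0:
                for i in range(n):
                    for q in range(6):
                        yp[q, i] = y[q, i] + dt * d1[q, i]
                    yp[4, i] += A * a * sigma * sqdt * noise[0, step, i]
        for i in range(n):
            for q in range(6):
                y[q, i] += 0.5 * dt * (d1[q, i] + d2[q, i])
            y[4, i] += A * a * sigma * sqdt * noise[0, step, i]
        if (step + 1) % rec_every == 0:
            ok = True
            for i in range(n):
                out[i, j] = y[1, i] - y[2, i]
                if not np.isfinite(out[i, j]):
                    ok = False
            if not ok:
                fail = step
                break
            j += 1
    return out, fail


def simulate_jansen_rit(
    sc: StructuralConnectome,
    params: JansenRitParams,
    duration: float,
    dt: float = 1e-4,
    seed: int = 0,
    record_every: int = 1,
    init_scale: float = 0.01,
    region_offset: int = 0,
) -> SimulationResult:
    """Integrate the Jansen-Rit network; observable is y1 - y2 (mV)."""
    if not sc.normalized:
        raise PreconditionError("connectome must be normalized before simulation")
    n = sc.n_regions
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise PreconditionError("duration shorter than one step")
    C = params.c_vector(n)
    noise, init = noise_streams(seed, n, n_steps, n_channels=1, n_init=3,
                                region_offset=region_offset)
    y0 = np.zeros((6, n))
    y0[:3] = init * init_scale
    out, fail = _jr_core(
        sc.weights, params.A, params.B, params.a, params.b, params.v_max,
        params.v0, params.r, C, params.G, params.P, params.sigma,
        dt, n_steps, record_every, noise, y0,
    )
    check_finite(out, "jansen_rit", fail)
    rec_dt = dt * record_every
    time = rec_dt * np.arange(1, out.shape[1] + 1)
    return SimulationResult(
        time=time, states=out, dt=rec_dt, model_id="jansen_rit",
        seed=seed, params_digest=params_digest(params), time_unit="s",
    )
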