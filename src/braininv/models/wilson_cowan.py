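"""Wilson-Cowan excitatory/inhibitory neural-mass network.

Each region holds one excitatory (E) and one inhibitory (I) population with
sigmoidal transfer functions; regions interact through the connectome in the
excitatory and (optionally) inhibitory input sums. Observable: E.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ..connectome import StructuralConnectome
from ..errors import PreconditionError
from .base import SimulationResult, check_finite, noise_streams, params_digest

__all__ = ["WilsonCowanParams", "sigmoid_wc", "simulate_wilson_cowan"]


@dataclass
class WilsonCowanParams:
    """Parameters of the Wilson-Cowan network model (nominal cortical set).

    Time is measured in the population time-constant unit (tau_e = tau_i = 8).
    ``P`` and ``Q`` are per-region external inputs, broadcast from scalars.
    """

    c_ee: float = 16.0
    c_ei: float = 12.0
    c_ie: float = 15.0
    c_ii: float = 3.0
    tau_e: float = 8.0
    tau_i: float = 8.0
    a_e: float = 1.3
    a_i: float = 2.0
    b_e: float = 4.0
    b_i: float = 3.7
    c_e: float = 1.0
    c_i: float = 1.0
    theta_e: float = 0.0
    theta_i: float = 0.0
    r_e: float = 1.0
    r_i: float = 1.0
    k_e: float = 0.994
    k_i: float = 0.999
    alpha_e: float = 1.0
    alpha_i: float = 1.0
    P: np.ndarray | float = 0.0
    Q: np.ndarray | float = 0.0
    g_e: float = 0.0
    g_i: float = 0.0
    sigma: float = 0.005
    shifted_sigmoid: bool = True

    def __post_init__(self):
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise PreconditionError("tau_e and tau_i must be positive")
        if self.sigma < 0:
            raise PreconditionError("sigma must be non-negative")

    def vectors(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        P = np.broadcast_to(np.asarray(self.P, dtype=float), (n,)).copy()
        Q = np.broadcast_to(np.asarray(self.Q, dtype=float), (n,)).copy()
        return P, Q


def sigmoid_wc(x, side: str, params: WilsonCowanParams):
    """Sigmoidal transfer function S_k(x) for population ``side`` in {'e','i'}.

    The shifted form subtracts the logistic value at x = 0, so S(0) = 0 and
    the resting origin is a fixed point; the plain form is the raw logistic.
    """
    if side not in ("e", "i"):
        raise PreconditionError("side must be 'e' or 'i'")
    a = params.a_e if side == "e" else params.a_i
    b = params.b_e if side == "e" else params.b_i
    c = params.c_e if side == "e" else params.c_i
    x = np.asarray(x, dtype=float)
    plain = c / (1.0 + np.exp(-a * (x - b)))
    if params.shifted_sigmoid:
        return plain - c / (1.0 + np.exp(a * b))
    return plain


@njit(cache=True)
def _wc_core(W, cee, cei, cie, cii, taue, taui, ae, ai, be, bi, ce, ci,
             the, thi, re_, ri_, ke, ki, ale, ali, P, Q, ge, gi, sigma,
             shifted, dt, n_steps, rec_every, noise, E0, I0):
    n = W.shape[0]
    n_rec = n_steps // rec_every
    E_rec = np.empty((n, n_rec))
    I_rec = np.empty((n, n_rec))
    E = E0.copy()
    I = I0.copy()
    dE = np.empty(n)
    dI = np.empty(n)
    dE2 = np.empty(n)
    dI2 = np.empty(n)
    Ep = np.empty(n)
    Ip = np.empty(n)
    sqdt = np.sqrt(dt)
    off_e = ce / (1.0 + np.exp(ae * be)) if shifted else 0.0
    off_i = ci / (1.0 + np.exp(ai * bi)) if shifted else 0.0
    fail = -1
    j = 0
    for step in range(n_steps):
        for k in range(n):
            ce_in = 0.0
            ci_in = 0.0
            if ge != 0.0 or gi != 0.0:
                for l in range(n):
                    ce_in += W[k, l] * E[l]
                    ci_in += W[k, l] * I[l]
            xe = ale * (cee * E[k] - cei * I[k] + P[k] - the + ge * ce_in)
            xi = ali * (cie * E[k] - cii * I[k] + Q[k] - thi + gi * ci_in)
            Se = ce / (1.0 + np.exp(-ae * (xe - be))) - off_e
            Si = ci / (1.0 + np.exp(-ai * (xi - bi))) - off_i
            dE[k] = (-E[k] + (ke - re_ * E[k]) * Se) / taue
            dI[k] = (-I[k] + (ki - ri_ * I[k]) * Si) / taui
        for k in range(n):
            Ep[k] = E[k] + dt * dE[k] + sigma / taue * sqdt * noise[0, step, k]
            Ip[k] = I[k] + dt * dI[k] + sigma / taui * sqdt * noise[1, step, k]
        for k in range(n):
            ce_in = 0.0
            ci_in = 0.0
            if ge != 0.0 or gi != 0.0:
                for l in range(n):
                    ce_in += W[k, l] * Ep[l]
                    ci_in += W[k, l] * Ip[l]
            xe = ale * (cee * Ep[k] - cei * Ip[k] + P[k] - the + ge * ce_in)
            xi = ali * (cie * Ep[k] - cii * Ip[k] + Q[k] - thi + gi * ci_in)
            Se = ce / (1.0 + np.exp(-ae * (xe - be))) - off_e
            Si = ci / (1.0 + np.exp(-ai * (xi - bi))) - off_i
            dE2[k] = (-Ep[k] + (ke - re_ * Ep[k]) * Se) / taue
            dI2[k] = (-Ip[k] + (ki - ri_ * Ip[k]) * Si) / taui
        for k in range(n):
            E[k] += 0.5 * dt * (dE[k] + dE2[k]) + sigma / taue * sqdt * noise[0, step, k]
            I[k] += 0.5 * dt * (dI[k] + dI2[k]) + sigma / taui * sqdt * noise[1, step, k]
        if (step + 1) % rec_every == 0:
            ok = True
            for k in range(n):
                E_rec[k, j] = E[k]
                I_rec[k, j] = I[k]
                if not (np.isfinite(E[k]) and np.isfinite(I[k])):
                    ok = False
            if not ok:
                fail = step
                break
            j += 1
    return E_rec, I_rec, fail


def simulate_wilson_cowan(
    sc: StructuralConnectome,
    params: WilsonCowanParams,
    duration: float,
    dt: float = 0.05,
    seed: int = 0,
    record_every: int = 1,
    init_scale: float = 0.01,
    region_offset: int = 0,
) -> SimulationResult:
    """Integrate the Wilson-Cowan network; observable is E (I in extras).

    Initial E, I are small positive perturbations (|N(0, init_scale)|) around
    the resting origin, drawn from each region's own seed substream.
    """
    if not sc.normalized:
        raise PreconditionError("connectome must be normalized before simulation")
    n = sc.n_regions
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise PreconditionError("duration shorter than one step")
    P, Q = params.vectors(n)
    noise, init = noise_streams(seed, n, n_steps, n_channels=2, n_init=2,
                                region_offset=region_offset)
    E0 = np.abs(init[0]) * init_scale
    I0 = np.abs(init[1]) * init_scale
    E_rec, I_rec, fail = _wc_core(
        sc.weights, params.c_ee, params.c_ei, params.c_ie, params.c_ii,
        params.tau_e, params.tau_i, params.a_e, params.a_i, params.b_e,
        params.b_i, params.c_e, params.c_i, params.theta_e, params.theta_i,
        params.r_e, params.r_i, params.k_e, params.k_i, params.alpha_e,
        params.alpha_i, P, Q, params.g_e, params.g_i, params.sigma,
        params.shifted_sigmoid, dt, n_steps, record_every, noise, E0, I0,
    )
    check_finite(E_rec, "wilson_cowan", fail)
    rec_dt = dt * record_every
    time = rec_dt * np.arange(1, E_rec.shape[1] + 1)
    return SimulationResult(
        time=time, states=E_rec, dt=rec_dt, model_id="wilson_cowan",
        seed=seed, params_digest=params_digest(params), time_unit="tau",
        extras={"I": I_rec},
    )
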