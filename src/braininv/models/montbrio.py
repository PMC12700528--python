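"""Montbrio-Pazo-Roxin exact mean-field network (fMRI-oriented).

Per region, the exact macroscopic limit of a population of quadratic
integrate-and-fire neurons with Lorentzian-distributed excitability: firing
rate r and mean membrane potential v. With the nominal parameter set each
isolated node is bistable (low-firing down-state fixed point, high-firing
up-state focus); dynamical noise on v drives switching, which is the source
of fMRI-like functional connectivity dynamics. The Delta/(pi*tau) term repels
r = 0, so r stays positive; the integrator enforces this by retrying a
violating step once at half step size. Noise enters only the v equation.
Recorded states are bin averages over ``record_every`` steps, which both
limits memory and provides the integrated synaptic activity driving the
hemodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ..connectome import StructuralConnectome
from ..errors import IntegratorStepError, PreconditionError
from .base import SimulationResult, check_finite, noise_streams, params_digest

__all__ = ["MontbrioParams", "simulate_montbrio"]


@dataclass
class MontbrioParams:
    """Montbrio model parameters; time in ms.

    ``eta`` is the per-region excitability (broadcastable scalar); ``I_stim``
    an optional (N, T_steps) or scalar stimulation current; ``sigma`` the SD
    of the Gaussian noise on the membrane-potential equation.
    """

    tau: float = 1.0
    J: float = 14.5
    Delta: float = 0.7
    eta: np.ndarray | float = -4.6
    G: float = 0.56
    I_stim: np.ndarray | float = 0.0
    sigma: float = 0.037

    def __post_init__(self):
        if self.Delta <= 0:
            raise PreconditionError("Delta must be positive")
        if self.tau <= 0:
            raise PreconditionError("tau must be positive")
        if self.sigma < 0:
            raise PreconditionError("sigma must be non-negative")

    def eta_vector(self, n: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.eta, dtype=float), (n,)).copy()


@njit(cache=True)
def _mpr_drift(r, v, W, tau, J, Delta, eta, G, I_ext, dr, dv):
    n = r.shape[0]
    pt = np.pi * tau
    for i in range(n):
        coup = 0.0
        if G != 0.0:
            for k in range(n):
                coup += W[i, k] * r[k]
        dr[i] = (2.0 * r[i] * v[i] + Delta / pt) / tau
        dv[i] = (v[i] * v[i] - (pt * r[i]) ** 2 + J * tau * r[i]
                 + eta[i] + G * coup + I_ext[i]) / tau


@njit(cache=True)
def _mpr_core(W, tau, J, Delta, eta, G, I_stim, sigma, dt, n_steps,
              rec_every, noise, r0, v0):
    n = W.shape[0]
    n_rec = n_steps // rec_every
    r_rec = np.zeros((n, n_rec))
    v_rec = np.zeros((n, n_rec))
    r = r0.copy()
    v = v0.copy()
    dr1 = np.empty(n)
    dv1 = np.empty(n)
    dr2 = np.empty(n)
    dv2 = np.empty(n)
    rp = np.empty(n)
    vp = np.empty(n)
    rn = np.empty(n)
    vn = np.empty(n)
    I_ext = np.empty(n)
    fail = -1
    j = 0
    inv_rec = 1.0 / rec_every
    for step in range(n_steps):
        for i in range(n):
            I_ext[i] = I_stim[i, step] if I_stim.shape[1] > 1 else I_stim[i, 0]
        # full Heun step
        _mpr_drift(r, v, W, tau, J, Delta, eta, G, I_ext, dr1, dv1)
        amp = sigma / tau * np.sqrt(dt)
        for i in range(n):
            rp[i] = r[i] + dt * dr1[i]
            vp[i] = v[i] + dt * dv1[i] + amp * noise[0, step, i]
        _mpr_drift(rp, vp, W, tau, J, Delta, eta, G, I_ext, dr2, dv2)
        bad = False
        for i in range(n):
            rn[i] = r[i] + 0.5 * dt * (dr1[i] + dr2[i])
            vn[i] = v[i] + 0.5 * dt * (dv1[i] + dv2[i]) + amp * noise[0, step, i]
            if rn[i] <= 0.0 or not np.isfinite(rn[i]):
                bad = True
        if bad:
            # one retry: two half steps sharing the step's noise increment
            hdt = 0.5 * dt
            hamp = sigma / tau * np.sqrt(hdt) / np.sqrt(2.0)
            for i in range(n):
                rn[i] = r[i]
                vn[i] = v[i]
            ok = True
            for half in range(2):
                _mpr_drift(rn, vn, W, tau, J, Delta, eta, G, I_ext, dr1, dv1)
                for i in range(n):
                    rp[i] = rn[i] + hdt * dr1[i]
                    vp[i] = vn[i] + hdt * dv1[i] + hamp * noise[0, step, i]
                _mpr_drift(rp, vp, W, tau, J, Delta, eta, G, I_ext, dr2, dv2)
                for i in range(n):
                    rn[i] = rn[i] + 0.5 * hdt * (dr1[i] + dr2[i])
                    vn[i] = vn[i] + 0.5 * hdt * (dv1[i] + dv2[i]) + hamp * noise[0, step, i]
                    if rn[i] <= 0.0 or not np.isfinite(rn[i]):
                        ok = False
            if not ok:
                fail = step
                break
        for i in range(n):
            r[i] = rn[i]
            v[i] = vn[i]
            r_rec[i, j] += r[i] * inv_rec
            v_rec[i, j] += v[i] * inv_rec
        if (step + 1) % rec_every == 0:
            j += 1
            if j >= n_rec:
                break
    return r_rec, v_rec, fail


def simulate_montbrio(
    sc: StructuralConnectome,
    params: MontbrioParams,
    duration: float,
    dt: float = 0.01,
    seed: int = 0,
    record_every: int = 1,
    r0: np.ndarray | float | None = None,
    v0: np.ndarray | float | None = None,
    init_scale: float = 0.01,
    region_offset: int = 0,
) -> SimulationResult:
    """Integrate the Montbrio network; observable r, extras v (bin averages).

    ``duration`` and ``dt`` in ms. Default initial conditions are near the
    down state (r = 0.05 + |eps|, v = -2.0 + eps) with per-region
    perturbations from the seed stream.
    """
    if not sc.normalized:
        raise PreconditionError("connectome must be normalized before simulation")
    n = sc.n_regions
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise PreconditionError("duration shorter than one step")
    eta = params.eta_vector(n)
    stim = np.asarray(params.I_stim, dtype=float)
    if stim.ndim == 0:
        stim = np.full((n, 1), float(stim))
    elif stim.ndim == 1:
        stim = stim[:, None].copy()
    noise, init = noise_streams(seed, n, n_steps, n_channels=1, n_init=2,
                                region_offset=region_offset)
    ri = (0.05 + np.abs(init[0]) * init_scale if r0 is None
          else np.broadcast_to(np.asarray(r0, dtype=float), (n,)).copy())
    vi = (-2.0 + init[1] * init_scale if v0 is None
          else np.broadcast_to(np.asarray(v0, dtype=float), (n,)).copy())
    if np.any(ri <= 0):
        raise PreconditionError("initial firing rate must be positive")
    r_rec, v_rec, fail = _mpr_core(
        sc.weights, params.tau, params.J, params.Delta, eta, params.G,
        stim, params.sigma, dt, n_steps, record_every, noise, ri, vi,
    )
    if fail >= 0:
        raise IntegratorStepError(
            f"montbrio: r <= 0 at step {fail} even after dt/2 retry; "
            "use a smaller dt", step=fail,
        )
    check_finite(r_rec, "montbrio")
    rec_dt = dt * record_every
    time = rec_dt * np.arange(1, r_rec.shape[1] + 1)
    return SimulationResult(
        time=time, states=r_rec, dt=rec_dt, model_id="montbrio",
        seed=seed, params_digest=params_digest(params), time_unit="ms",
        extras={"v": v_rec},
    )
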