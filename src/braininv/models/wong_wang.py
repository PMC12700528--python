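"""Reduced Wong-Wang (parameterized dynamic mean-field) network.

One synaptic gating variable S per region, driven by the sigmoidal-like
transfer function H(x) with a removable singularity at a*x = b (H -> 1/d
there, handled by a guarded series branch). The pDMF parameterization
expresses the per-region recurrent strength w_i, external input I_i, and
noise amplitude sigma_i as linear combinations of two anatomical maps
(T1w/T2w myelin and the first FC principal gradient), reducing 3N regional
parameters to 9 coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ..connectome import StructuralConnectome
from ..errors import PreconditionError, ValidationError
from .base import SimulationResult, check_finite, noise_streams, params_digest

__all__ = [
    "WongWangParams",
    "PDMFCoefficients",
    "transfer_h",
    "pdmf_expand",
    "simulate_wong_wang",
]


@dataclass
class WongWangParams:
    """Reduced Wong-Wang parameters; time in ms, currents in nA.

    ``w``, ``I``, and ``sigma`` are per-region (broadcastable from scalars);
    ``gamma`` is per ms (0.641/1000), ``d`` in seconds as printed.
    """

    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma: float = 0.641e-3
    tau_s: float = 100.0
    J: float = 0.2609
    w: np.ndarray | float = 0.6
    I: np.ndarray | float = 0.3
    G: float = 6.28
    sigma: np.ndarray | float = 0.005

    def __post_init__(self):
        if self.tau_s <= 0:
            raise PreconditionError("tau_s must be positive")
        if self.d <= 0:
            raise PreconditionError("d must be positive")

    def vectors(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = np.broadcast_to(np.asarray(self.w, dtype=float), (n,)).copy()
        I = np.broadcast_to(np.asarray(self.I, dtype=float), (n,)).copy()
        s = np.broadcast_to(np.asarray(self.sigma, dtype=float), (n,)).copy()
        if np.any(s < 0):
            raise PreconditionError("sigma must be non-negative")
        return w, I, s


@dataclass
class PDMFCoefficients:
    """Linear map from anatomical maps to regional (w, I, sigma).

    w_i = a_w Mye_i + b_w Grad_i + c_w, and likewise for I and sigma.
    """

    a_w: float = 0.0
    b_w: float = 0.0
    c_w: float = 0.6
    a_I: float = 0.0
    b_I: float = 0.0
    c_I: float = 0.3
    a_sigma: float = 0.0
    b_sigma: float = 0.0
    c_sigma: float = 0.005
    mye: np.ndarray = field(default_factory=lambda: np.zeros(0))
    grad: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        mye = np.asarray(self.mye, dtype=float)
        grad = np.asarray(self.grad, dtype=float)
        if mye.shape != grad.shape or mye.ndim != 1:
            raise ValidationError("mye and grad must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(mye)) and np.all(np.isfinite(grad))):
            raise ValidationError("anatomical maps must be finite")
        object.__setattr__(self, "mye", mye)
        object.__setattr__(self, "grad", grad)


def pdmf_expand(coeffs: PDMFCoefficients) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand 9 pDMF coefficients into per-region (w, I, sigma) vectors.

    Values are returned as computed by the linear maps; any clipping to
    physical ranges is the simulator's contract, not this function's.
    """
    m, g = coeffs.mye, coeffs.grad
    w = coeffs.a_w * m + coeffs.b_w * g + coeffs.c_w
    I = coeffs.a_I * m + coeffs.b_I * g + coeffs.c_I
    sigma = coeffs.a_sigma * m + coeffs.b_sigma * g + coeffs.c_sigma
    return w, I, sigma


@njit(cache=True)
def _h_scalar(x, a, b, d):
    u = a * x - b
    s = d * u
    if abs(s) < 1e-6:  # removable singularity at a*x = b
        return 1.0 / d + 0.5 * u + d * u * u / 12.0
    return u / (1.0 - np.exp(-s))


def transfer_h(x, a: float = 270.0, b: float = 108.0, d: float = 0.154):
    """Firing-rate transfer H(x) = (a x - b)/(1 - exp(-d (a x - b))) in Hz."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    for i, xi in np.ndenumerate(x):
        out[i] = _h_scalar(xi, a, b, d)
    return out if out.size > 1 else float(out[0])


@njit(cache=True)
def _ww_core(W, a, b, d, gamma, tau_s, J, wvec, Ivec, G, svec, dt, n_steps,
             rec_every, noise, S0):
    n = W.shape[0]
    n_rec = n_steps // rec_every
    out = np.empty((n, n_rec))
    S = S0.copy()
    d1 = np.empty(n)
    d2 = np.empty(n)
    Sp = np.empty(n)
    sqdt = np.sqrt(dt)
    fail = -1
    j = 0
    for step in range(n_steps):
        for i in range(n):
            coup = 0.0
            if G != 0.0:
                for k in range(n):
                    coup += W[i, k] * S[k]
            x = wvec[i] * J * S[i] + G * J * coup + Ivec[i]
            d1[i] = -S[i] / tau_s + (1.0 - S[i]) * gamma * _h_scalar(x, a, b, d)
        for i in range(n):
            Sp[i] = S[i] + dt * d1[i] + svec[i] * sqdt * noise[0, step, i]
            if Sp[i] < 0.0:
                Sp[i] = 0.0
            elif Sp[i] > 1.0:
                Sp[i] = 1.0
        for i in range(n):
            coup = 0.0
            if G != 0.0:
                for k in range(n):
                    coup += W[i, k] * Sp[k]
            x = wvec[i] * J * Sp[i] + G * J * coup + Ivec[i]
            d2[i] = -Sp[i] / tau_s + (1.0 - Sp[i]) * gamma * _h_scalar(x, a, b, d)
        for i in range(n):
            S[i] += 0.5 * dt * (d1[i] + d2[i]) + svec[i] * sqdt * noise[0, step, i]
            if S[i] < 0.0:  # clip to the physical gating range
                S[i] = 0.0
            elif S[i] > 1.0:
                S[i] = 1.0
        if (step + 1) % rec_every == 0:
            ok = True
            for i in range(n):
                out[i, j] = S[i]
                if not np.isfinite(S[i]):
                    ok = False
            if not ok:
                fail = step
                break
            j += 1
    return out, fail


def simulate_wong_wang(
    sc: StructuralConnectome,
    params: WongWangParams,
    duration: float,
    dt: float = 1.0,
    seed: int = 0,
    record_every: int = 1,
    S0: np.ndarray | float | None = None,
    init_scale: float = 0.001,
    region_offset: int = 0,
) -> SimulationResult:
    """Integrate the reduced Wong-Wang network; observable is S in [0, 1].

    ``duration`` and ``dt`` in ms. S is clipped to [0, 1] after each stage.
    """
    if not sc.normalized:
        raise PreconditionError("connectome must be normalized before simulation")
    n = sc.n_regions
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise PreconditionError("duration shorter than one step")
    wvec, Ivec, svec = params.vectors(n)
    noise, init = noise_streams(seed, n, n_steps, n_channels=1, n_init=1,
                                region_offset=region_offset)
    Si = (np.clip(0.1 + init[0] * init_scale, 0.0, 1.0) if S0 is None
          else np.broadcast_to(np.asarray(S0, dtype=float), (n,)).copy())
    out, fail = _ww_core(
        sc.weights, params.a, params.b, params.d, params.gamma, params.tau_s,
        params.J, wvec, Ivec, params.G, svec, dt, n_steps, record_every,
        noise, Si,
    )
    check_finite(out, "wong_wang", fail)
    rec_dt = dt * record_every
    time = rec_dt * np.arange(1, out.shape[1] + 1)
    return SimulationResult(
        time=time, states=out, dt=rec_dt, model_id="wong_wang",
        seed=seed, params_digest=params_digest(params), time_unit="ms",
    )
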