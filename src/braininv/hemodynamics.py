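"""Balloon-Windkessel hemodynamic model: neural activity to BOLD.

Neurovascular coupling per region: a vasodilatory signal s driven by neural
activity x(t) raises blood inflow f, which inflates venous volume v and
washes out deoxyhemoglobin q; the BOLD readout mixes (1-q), (1-q/v), and
(1-v) with field-dependent constants k1-k3. Rest (s=0, f=v=q=1) is an exact
fixed point, so zero input yields exactly zero BOLD. Two distinct epsilons
appear in the literature and are kept as separate fields: the neuronal
efficacy (epsilon_eff, in the state equations) and the intra/extravascular
signal ratio (epsilon_ratio, in k2 and k3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import DivergenceError, PreconditionError
from .models.base import SimulationResult

__all__ = ["BalloonParams", "BoldResult", "balloon_constants", "bold_forward"]


@dataclass
class BalloonParams:
    """Hemodynamic parameters (1.5 T nominal set); times in seconds."""

    tau_s: float = 1.5
    tau_f: float = 4.5
    alpha: float = 0.2
    tau_0: float = 1.0
    epsilon_eff: float = 0.1
    r_0: float = 25.0
    vartheta_0: float = 40.3
    epsilon_ratio: float = 1.43
    V_0: float = 0.02
    E_0: float = 0.8
    TE: float = 0.04
    TR: float = 2.0

    def __post_init__(self):
        for name in ("tau_s", "tau_f", "tau_0", "TR"):
            if getattr(self, name) <= 0:
                raise PreconditionError(f"{name} must be positive")
        if not 0 < self.E_0 < 1:
            raise PreconditionError("E_0 must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise PreconditionError("alpha must lie in (0, 1)")


@dataclass
class BoldResult:
    """BOLD signal change per region on a TR-spaced grid (seconds)."""

    time: np.ndarray
    bold: np.ndarray
    TR: float


def balloon_constants(params: BalloonParams) -> tuple[float, float, float]:
    """BOLD readout constants (k1, k2, k3) for the given acquisition."""
    k1 = 4.3 * params.vartheta_0 * params.E_0 * params.TE
    k2 = params.epsilon_ratio * params.r_0 * params.E_0 * params.TE
    k3 = 1.0 - params.epsilon_ratio
    return k1, k2, k3


@njit(cache=True)
def _balloon_core(x, dt, tau_s, tau_f, alpha, tau_0, eps, E_0):
    n, T = x.shape
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    out_v = np.empty((n, T))
    out_q = np.empty((n, T))
    ia = 1.0 / alpha
    fail = -1
    for t in range(T):
        for i in range(n):
            # Heun predictor-corrector on (s, f, v, q)
            ds1 = eps * x[i, t] - s[i] / tau_s - (f[i] - 1.0) / tau_f
            df1 = s[i]
            dv1 = (f[i] - v[i] ** ia) / tau_0
            dq1 = (f[i] * (1.0 - (1.0 - E_0) ** (1.0 / f[i])) / E_0
                   - v[i] ** ia * q[i]) / tau_0
            sp = s[i] + dt * ds1
            fp = f[i] + dt * df1
            vp = v[i] + dt * dv1
            qp = q[i] + dt * dq1
            if vp <= 0.0 or qp <= 0.0 or fp <= 0.0:
                fail = t
                break
            ds2 = eps * x[i, t] - sp / tau_s - (fp - 1.0) / tau_f
            df2 = sp
            dv2 = (fp - vp ** ia) / tau_0
            dq2 = (fp * (1.0 - (1.0 - E_0) ** (1.0 / fp)) / E_0
                   - vp ** ia * qp) / tau_0
            s[i] += 0.5 * dt * (ds1 + ds2)
            f[i] += 0.5 * dt * (df1 + df2)
            v[i] += 0.5 * dt * (dv1 + dv2)
            q[i] += 0.5 * dt * (dq1 + dq2)
            if v[i] <= 0.0 or q[i] <= 0.0:
                fail = t
                break
            out_v[i, t] = v[i]
            out_q[i, t] = q[i]
        if fail >= 0:
            break
    return out_v, out_q, s, f, fail


def bold_forward(
    activity: SimulationResult,
    params: BalloonParams,
    transient_fraction: float = 0.1,
    gain: float = 1.0,
    center: bool = False,
) -> BoldResult:
    """Map a neural SimulationResult to BOLD, sampled at TR.

    The balloon states are integrated at the dt of ``activity`` (converted to
    seconds from its recorded unit). The neural drive is the model observable,
    optionally mean-centered (``center``) and scaled by ``gain``. The first
    ``transient_fraction`` of the signal (in time) is discarded before
    TR-sampling, yielding floor(kept_duration / TR) output samples.
    """
    x = activity.states
    if not np.all(np.isfinite(x)):
        raise PreconditionError("activity contains non-finite values")
    unit = activity.time_unit
    scale = {"s": 1.0, "ms": 1e-3}.get(unit)
    if scale is None:
        raise PreconditionError(
            f"cannot convert time unit {unit!r} to seconds for hemodynamics"
        )
    dt = activity.dt * scale
    if params.TR < dt:
        raise PreconditionError("TR must be at least the activity dt")
    drive = x * gain
    if center:
        drive = (x - x.mean(axis=1, keepdims=True)) * gain

    out_v, out_q, _, f_end, fail = _balloon_core(
        drive, dt, params.tau_s, params.tau_f, params.alpha, params.tau_0,
        params.epsilon_eff, params.E_0,
    )
    if fail >= 0:
        raise DivergenceError(
            f"balloon model: non-physical volume/flow at step {fail}", step=fail
        )
    k1, k2, k3 = balloon_constants(params)
    y = params.V_0 * (k1 * (1.0 - out_q) + k2 * (1.0 - out_q / out_v)
                      + k3 * (1.0 - out_v))

    T = y.shape[1]
    cut = int(round(transient_fraction * T))
    kept = T - cut
    stride = params.TR / dt
    n_out = int(np.floor(kept * dt / params.TR))
    if n_out < 1:
        raise PreconditionError("signal too short for one TR sample")
    idx = cut + (np.round((np.arange(1, n_out + 1)) * stride).astype(int) - 1)
    idx = np.clip(idx, 0, T - 1)
    t_out = activity.time[idx] * scale
    return BoldResult(time=t_out, bold=y[:, idx], TR=params.TR)
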