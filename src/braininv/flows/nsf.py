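"""Conditional neural spline flow (piecewise rational-quadratic coupling).

Each transform splits the (standardized) parameter vector in two: one half
passes through unchanged and, together with the conditioning features, drives
a residual network that outputs monotone rational-quadratic spline parameters
(bin widths, heights, and internal knot derivatives) for the other half.
Splines act on [-B, B] with identity linear tails outside. Halves alternate
across transforms. Requires d >= 2 (a coupling split needs both halves).
"""

from __future__ import annotations

import numpy as np

from ..errors import CapabilityError, TrainingFailureError
from .autodiff import Tensor, concat, softmax, softplus, take_along
from .maf import _linear_init, _transpose

__all__ = ["ConditionalNSF"]

_LOG2PI = np.log(2.0 * np.pi)
_B = 3.0  # tail bound in standardized units
_MIN_W = 1e-3
_MIN_D = 1e-3


class _ResidualConditioner:
    """Linear -> ReLU -> two residual blocks -> linear head."""

    def __init__(self, n_in, hidden, n_out, rng):
        self.inp = _linear_init(rng, hidden, max(n_in, 1))
        self.blocks = [
            (_linear_init(rng, hidden, hidden), _linear_init(rng, hidden, hidden))
            for _ in range(2)
        ]
        self.out = _linear_init(rng, n_out, hidden)
        # start near the identity transform: zero the head
        self.out[0].data[:] = 0.0
        self.out[1].data[:] = 0.0

    def parameters(self):
        ps = list(self.inp)
        for (W1, b1), (W2, b2) in self.blocks:
            ps += [W1, b1, W2, b2]
        ps += list(self.out)
        return ps

    def forward(self, h: Tensor) -> Tensor:
        W, b = self.inp
        h = (h @ _transpose(W) + b).relu()
        for (W1, b1), (W2, b2) in self.blocks:
            inner = (h @ _transpose(W1) + b1).relu()
            h = (h + (inner @ _transpose(W2) + b2)).relu()
        W, b = self.out
        return h @ _transpose(W) + b


def _spline_params(raw: Tensor, n_dim: int, K: int):
    """Split conditioner output into normalized widths/heights/derivatives."""
    B = raw.shape[0]
    raw = raw.reshape(B, n_dim, 3 * K - 1)
    w = softmax(raw[:, :, :K], axis=-1)
    h = softmax(raw[:, :, K:2 * K], axis=-1)
    # regularized bin sizes in [-B, B]
    w = (w * (1.0 - K * _MIN_W) + _MIN_W) * (2 * _B)
    h = (h * (1.0 - K * _MIN_W) + _MIN_W) * (2 * _B)
    d = softplus(raw[:, :, 2 * K:]) + _MIN_D  # K-1 internal derivatives
    return w, h, d


def _cumsum(t: Tensor) -> Tensor:
    K = t.shape[-1]
    tri = np.triu(np.ones((K, K)))
    return t @ Tensor(tri)


def _rqs_forward(zt: Tensor, w: Tensor, h: Tensor, d: Tensor, K: int):
    """Monotone RQ spline of zt (B, n) -> (y Tensor, logdet Tensor).

    Out-of-range entries map through the identity with zero log-derivative.
    Bin membership is piecewise constant, so the integer bin indices are
    computed outside the graph; the spline value stays differentiable in the
    input, the bin geometry, and the knot derivatives.
    """
    z = zt.data
    inside = (np.abs(z) < _B)
    zc = np.clip(z, -_B + 1e-9, _B - 1e-9)
    m_in = inside.astype(float)
    # inside entries keep the graph connection to zt; outside use constants
    zin = zt * Tensor(m_in) + Tensor(zc * (1.0 - m_in))

    cw = _cumsum(w)  # right knot positions - (-B)
    ch = _cumsum(h)
    xknots = cw.data - _B  # (B, n, K) right edges
    # bin index of each sample
    idx = (zc[..., None] > xknots[..., :-1]).sum(-1, dtype=np.int64)
    idx = np.clip(idx, 0, K - 1)

    ones = Tensor(np.ones(d.shape[:2] + (1,)))
    dfull = concat([ones, d, ones], axis=-1)  # boundary derivatives = 1

    iexp = idx[..., None]
    wk = take_along(w, iexp, axis=-1)[:, :, 0]
    hk = take_along(h, iexp, axis=-1)[:, :, 0]
    xk = take_along(cw, iexp, axis=-1)[:, :, 0] - Tensor(np.full(1, _B)) - wk
    yk = take_along(ch, iexp, axis=-1)[:, :, 0] - Tensor(np.full(1, _B)) - hk
    dk = take_along(dfull, iexp, axis=-1)[:, :, 0]
    dk1 = take_along(dfull, iexp + 1, axis=-1)[:, :, 0]

    sk = hk / wk
    xi = (zin - xk) / wk
    xi1 = 1.0 - xi
    xixi1 = xi * xi1
    num = hk * (sk * xi.square() + dk * xixi1)
    den = sk + (dk1 + dk - 2.0 * sk) * xixi1
    y_in = yk + num / den
    deriv_num = sk.square() * (dk1 * xi.square() + 2.0 * sk * xixi1 + dk * xi1.square())
    ld_in = deriv_num.log() - 2.0 * den.log()

    m = Tensor(m_in)
    y = y_in * m + zt * Tensor(1.0 - m_in)
    ld = ld_in * m
    return y, ld.sum(axis=1)


def _rqs_inverse(y: np.ndarray, w: np.ndarray, h: np.ndarray, d: np.ndarray, K: int):
    """Numpy-only inverse spline (for sampling)."""
    inside = np.abs(y) < _B
    yc = np.clip(y, -_B + 1e-9, _B - 1e-9)
    cw = np.cumsum(w, axis=-1)
    ch = np.cumsum(h, axis=-1)
    yknots = ch - _B
    idx = (yc[..., None] > yknots[..., :-1]).sum(-1)
    idx = np.clip(idx, 0, K - 1)
    dfull = np.concatenate([np.ones(d.shape[:2] + (1,)), d,
                            np.ones(d.shape[:2] + (1,))], axis=-1)
    take = lambda a, i: np.take_along_axis(a, i[..., None], axis=-1)[..., 0]
    wk, hk = take(w, idx), take(h, idx)
    xk = take(cw, idx) - _B - wk
    yk = take(ch, idx) - _B - hk
    dk, dk1 = take(dfull, idx), take(dfull, idx + 1)
    sk = hk / wk
    t = yc - yk
    a = hk * (sk - dk) + t * (dk1 + dk - 2 * sk)
    b = hk * dk - t * (dk1 + dk - 2 * sk)
    c = -sk * t
    disc = b**2 - 4 * a * c
    disc = np.maximum(disc, 0.0)
    xi = 2 * c / (-b - np.sqrt(disc))
    x = xk + xi * wk
    return np.where(inside, x, y)


class ConditionalNSF:
    """Stack of rational-quadratic coupling transforms conditioned on features."""

    family = "NSF"

    def __init__(self, d, m_context, n_transforms=5, hidden=50, n_bins=10, seed=0):
        if d < 2:
            raise CapabilityError(
                "the coupling-based spline flow needs at least 2 parameters; "
                "use the MAF family for 1-D problems"
            )
        rng = np.random.default_rng(seed)
        self.d = d
        self.m_context = m_context
        self.K = n_bins
        self.theta_mean = np.zeros(d)
        self.theta_std = np.ones(d)
        self.masks = []
        self.nets = []
        half = d // 2
        for t in range(n_transforms):
            mask = np.zeros(d, dtype=bool)
            if t % 2 == 0:
                mask[:half] = True  # True = identity half
            else:
                mask[half:] = True
            self.masks.append(mask)
            n_id = int(mask.sum())
            n_tr = d - n_id
            self.nets.append(
                _ResidualConditioner(n_id + m_context, hidden, n_tr * (3 * n_bins - 1), rng)
            )

    def set_standardization(self, mean, std):
        self.theta_mean = np.asarray(mean, dtype=float)
        std = np.asarray(std, dtype=float)
        self.theta_std = np.where(std > 0, std, 1.0)

    def parameters(self):
        ps = []
        for net in self.nets:
            ps += net.parameters()
        return ps

    def log_prob_tensor(self, theta: Tensor, x: np.ndarray | None, training=False) -> Tensor:
        xt = Tensor(x) if (x is not None and self.m_context) else None
        z = (theta - Tensor(self.theta_mean)) * Tensor(1.0 / self.theta_std)
        logdet = Tensor(-np.log(self.theta_std).sum())
        for mask, net in zip(self.masks, self.nets):
            id_idx = np.flatnonzero(mask)
            tr_idx = np.flatnonzero(~mask)
            z_id = z[:, id_idx]
            z_tr = z[:, tr_idx]
            cond_in = concat([z_id, xt], axis=1) if xt is not None else z_id
            raw = net.forward(cond_in)
            w, h, d = _spline_params(raw, len(tr_idx), self.K)
            y_tr, ld = _rqs_forward(z_tr, w, h, d, self.K)
            # reassemble in original dimension order
            pieces = [None] * self.d
            for j, dim in enumerate(id_idx):
                pieces[dim] = z_id[:, j:j + 1]
            for j, dim in enumerate(tr_idx):
                pieces[dim] = y_tr[:, j:j + 1]
            z = concat(pieces, axis=1)
            logdet = logdet + ld
        base = (z.square() + _LOG2PI).sum(axis=1) * (-0.5)
        return base + logdet

    def log_prob(self, theta, x):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if x is not None:
            x = np.broadcast_to(np.atleast_2d(x), (theta.shape[0], self.m_context))
        return self.log_prob_tensor(Tensor(theta), x).data

    def log_prob_grad(self, theta, x):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if x is not None:
            x = np.broadcast_to(np.atleast_2d(x), (theta.shape[0], self.m_context))
        t = Tensor(theta, requires_grad=True)
        lp = self.log_prob_tensor(t, x)
        lp.sum().backward()
        return lp.data, t.grad

    def sample(self, n: int, x, rng: np.random.Generator) -> np.ndarray:
        u = rng.standard_normal((n, self.d))
        if x is not None and self.m_context:
            xB = np.broadcast_to(np.atleast_2d(np.asarray(x, dtype=float)),
                                 (n, self.m_context))
            xt = Tensor(xB)
        else:
            xt = None
        z = u
        for mask, net in zip(reversed(self.masks), reversed(self.nets)):
            id_idx = np.flatnonzero(mask)
            tr_idx = np.flatnonzero(~mask)
            z_id = z[:, id_idx]
            cond_in = (concat([Tensor(z_id), xt], axis=1) if xt is not None
                       else Tensor(z_id))
            raw = net.forward(cond_in)
            w, h, d = _spline_params(raw, len(tr_idx), self.K)
            x_tr = _rqs_inverse(z[:, tr_idx], w.data, h.data, d.data, self.K)
            out = np.empty_like(z)
            out[:, id_idx] = z_id
            out[:, tr_idx] = x_tr
            z = out
        theta = z * self.theta_std + self.theta_mean
        if not np.all(np.isfinite(theta)):
            raise TrainingFailureError("flow produced non-finite samples")
        return theta
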