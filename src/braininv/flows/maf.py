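"""Conditional masked autoregressive flow (MAF).

Each of the stacked transforms is a MADE-style masked MLP producing
per-dimension shift mu_j and log-scale alpha_j from the preceding dimensions
theta_<j and the conditioning features x; the density-direction map is
u_j = (theta_j - mu_j) exp(-alpha_j) with log-determinant -sum(alpha). A
batch-normalization flow layer follows every transform, and dimension order
is reversed between transforms. The base density is standard normal. A fixed
affine standardization of theta (training-set mean/SD) is prepended, an exact
reparameterization with constant Jacobian.
"""

from __future__ import annotations

import numpy as np

from ..errors import TrainingFailureError
from .autodiff import Tensor

__all__ = ["ConditionalMAF"]

_LOG2PI = np.log(2.0 * np.pi)
_ALPHA_CAP = 5.0  # smooth cap on log-scales, keeps the transform invertible
_BN_EPS = 1e-5


def _linear_init(rng, n_out, n_in):
    w = rng.normal(0.0, 1.0 / np.sqrt(max(n_in, 1)), size=(n_out, n_in))
    return Tensor(w, requires_grad=True), Tensor(np.zeros(n_out), requires_grad=True)


class _MADE:
    """Masked conditioner emitting (mu, alpha); context enters the first layer."""

    def __init__(self, d, m_context, hidden, n_layers, rng):
        self.d = d
        deg_in = np.arange(1, d + 1)
        self.layers = []
        prev_deg = deg_in
        prev_n = d
        for _ in range(n_layers):
            deg_h = (np.arange(hidden) % max(d - 1, 1)) + 1
            mask = (deg_h[:, None] >= prev_deg[None, :]).astype(float)
            W, b = _linear_init(rng, hidden, prev_n)
            self.layers.append((W, b, mask, deg_h))
            prev_deg, prev_n = deg_h, hidden
        deg_out = np.tile(np.arange(1, d + 1), 2)  # [mu_1..mu_d, a_1..a_d]
        self.mask_out = (deg_out[:, None] > prev_deg[None, :]).astype(float)
        self.W_out, self.b_out = _linear_init(rng, 2 * d, prev_n)
        self.V_ctx, _ = _linear_init(rng, hidden, m_context) if m_context else (None, None)

    def parameters(self):
        ps = []
        for W, b, _, _ in self.layers:
            ps += [W, b]
        ps += [self.W_out, self.b_out]
        if self.V_ctx is not None:
            ps.append(self.V_ctx)
        return ps

    def forward(self, theta: Tensor, x: Tensor | None):
        h = theta
        for li, (W, b, mask, _) in enumerate(self.layers):
            Wm = W * Tensor(mask)
            pre = h @ _transpose(Wm) + b
            if li == 0 and self.V_ctx is not None and x is not None:
                pre = pre + x @ _transpose(self.V_ctx)
            h = pre.tanh()
        out = h @ _transpose(self.W_out * Tensor(self.mask_out)) + self.b_out
        mu = out[:, : self.d]
        raw = out[:, self.d:]
        alpha = raw.tanh() * _ALPHA_CAP  # smooth clamp of log-scale
        return mu, alpha


class _ContextMLP:
    """Unconditional-in-theta conditioner for d = 1 (depends on x only)."""

    def __init__(self, m_context, hidden, n_layers, rng):
        self.weights = []
        prev = max(m_context, 1)
        self.m_context = m_context
        for _ in range(n_layers):
            self.weights.append(_linear_init(rng, hidden, prev))
            prev = hidden
        self.out = _linear_init(rng, 2, prev)

    def parameters(self):
        ps = []
        for W, b in self.weights:
            ps += [W, b]
        ps += list(self.out)
        return ps

    def forward(self, theta: Tensor, x: Tensor | None):
        B = theta.shape[0]
        h = x if x is not None else Tensor(np.zeros((B, 1)))
        for W, b in self.weights:
            h = (h @ _transpose(W) + b).tanh()
        W, b = self.out
        out = h @ _transpose(W) + b
        mu = out[:, :1]
        alpha = out[:, 1:].tanh() * _ALPHA_CAP
        return mu, alpha


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T)
    out.requires_grad = t.requires_grad
    if out.requires_grad:
        out._prev = (t,)
        out._backward = lambda g: t._accum(np.asarray(g).T)
    return out


class _BatchNormFlow:
    """Invertible per-dimension batch normalization with running statistics."""

    def __init__(self, d, momentum=0.05):
        self.log_gamma = Tensor(np.zeros(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum

    def parameters(self):
        return [self.log_gamma, self.beta]

    def forward(self, u: Tensor, training: bool):
        if training:
            m = u.data.mean(axis=0)
            v = u.data.var(axis=0) + _BN_EPS
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v
        else:
            m, v = self.running_mean, self.running_var + _BN_EPS
        inv_sd = 1.0 / np.sqrt(v)
        y = (u - Tensor(m)) * Tensor(inv_sd) * self.log_gamma.exp() + self.beta
        # per-sample log|det| = sum_j (log_gamma_j - 0.5 log v_j)
        ld = self.log_gamma.sum() + Tensor(-0.5 * np.log(v).sum())
        return y, ld

    def inverse(self, y: np.ndarray) -> np.ndarray:
        v = self.running_var + _BN_EPS
        return (y - self.beta.data) * np.exp(-self.log_gamma.data) * np.sqrt(v) + self.running_mean


class ConditionalMAF:
    """Stack of masked autoregressive transforms conditioned on features.

    Parameters follow the common recipe for this architecture: 5 transforms,
    2 masked hidden layers of 50 tanh units each, batch normalization after
    each transform, reversed dimension order between transforms.
    """

    family = "MAF"

    def __init__(self, d, m_context, n_transforms=5, hidden=50, n_layers=2, seed=0):
        rng = np.random.default_rng(seed)
        self.d = d
        self.m_context = m_context
        self.theta_mean = np.zeros(d)
        self.theta_std = np.ones(d)
        self.mades = []
        self.bns = []
        for _ in range(n_transforms):
            if d == 1:
                self.mades.append(_ContextMLP(m_context, hidden, n_layers, rng))
            else:
                self.mades.append(_MADE(d, m_context, hidden, n_layers, rng))
            self.bns.append(_BatchNormFlow(d))
        self.perm = np.arange(d)[::-1]

    def set_standardization(self, mean, std):
        self.theta_mean = np.asarray(mean, dtype=float)
        std = np.asarray(std, dtype=float)
        self.theta_std = np.where(std > 0, std, 1.0)

    def parameters(self):
        ps = []
        for made, bn in zip(self.mades, self.bns):
            ps += made.parameters() + bn.parameters()
        return ps

    # ---- density direction ---------------------------------------------
    def log_prob_tensor(self, theta: Tensor, x: np.ndarray | None, training=False) -> Tensor:
        """Log density as a Tensor (differentiable w.r.t. theta and weights)."""
        xt = Tensor(x) if x is not None and self.m_context else None
        z = (theta - Tensor(self.theta_mean)) * Tensor(1.0 / self.theta_std)
        logdet = Tensor(-np.log(self.theta_std).sum())
        for made, bn in zip(self.mades, self.bns):
            mu, alpha = made.forward(z, xt)
            z = (z - mu) * (-alpha).exp()
            logdet = logdet + (-alpha).sum(axis=1)
            z, ld_bn = bn.forward(z, training)
            logdet = logdet + ld_bn
            z = z[:, self.perm]
        base = (z.square() + _LOG2PI).sum(axis=1) * (-0.5)
        return base + logdet

    def log_prob(self, theta: np.ndarray, x: np.ndarray | None) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if x is not None:
            x = np.broadcast_to(np.atleast_2d(x), (theta.shape[0], self.m_context))
        return self.log_prob_tensor(Tensor(theta), x).data

    def log_prob_grad(self, theta: np.ndarray, x: np.ndarray | None):
        """Returns (log q, d log q / d theta) for a batch of theta."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        if x is not None:
            x = np.broadcast_to(np.atleast_2d(x), (theta.shape[0], self.m_context))
        t = Tensor(theta, requires_grad=True)
        lp = self.log_prob_tensor(t, x)
        lp.sum().backward()
        return lp.data, t.grad

    # ---- sampling direction --------------------------------------------
    def sample(self, n: int, x: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
        u = rng.standard_normal((n, self.d))
        if x is not None and self.m_context:
            xB = np.broadcast_to(np.atleast_2d(np.asarray(x, dtype=float)),
                                 (n, self.m_context))
        else:
            xB = None
        inv_perm = np.argsort(self.perm)
        z = u
        for made, bn in zip(reversed(self.mades), reversed(self.bns)):
            z = z[:, inv_perm]
            z = bn.inverse(z)
            out = np.zeros_like(z)
            for j in range(self.d):  # sequential autoregressive inversion
                mu, alpha = made.forward(Tensor(out), Tensor(xB) if xB is not None else None)
                out[:, j] = z[:, j] * np.exp(alpha.data[:, j]) + mu.data[:, j]
            z = out
        theta = z * self.theta_std + self.theta_mean
        if not np.all(np.isfinite(theta)):
            raise TrainingFailureError("flow produced non-finite samples")
        return theta
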