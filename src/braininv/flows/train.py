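"""Maximum-likelihood training of conditional flows (Adam, early stopping).

Minimizes the negative conditional log-likelihood -sum_i log q(theta_i | x_i)
over the flow weights, with a validation split for early stopping. All
randomness (shuffling, split) comes from the training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import TrainingFailureError
from .autodiff import Tensor

__all__ = ["TrainConfig", "train_flow"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters for flow training."""

    batch_size: int = 256
    learning_rate: float = 5e-4
    max_epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    clip_norm: float = 5.0


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, clip_norm):
        self.t += 1
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad**2).sum())
        scale = 1.0
        norm = np.sqrt(total)
        if clip_norm and norm > clip_norm:
            scale = clip_norm / (norm + 1e-12)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def train_flow(flow, theta: np.ndarray, x: np.ndarray | None,
               config: TrainConfig | None = None) -> TrainHistory:
    """Train ``flow`` in place on aligned (theta, x) pairs; returns history."""
    config = config or TrainConfig()
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[0]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n))) if n >= 10 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    params = flow.parameters()
    opt = _Adam(params, config.learning_rate)
    hist = TrainHistory()
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    best_bn = _bn_state(flow)
    since_best = 0

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(tr_idx))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(tr_idx), config.batch_size):
            idx = tr_idx[perm[start:start + config.batch_size]]
            if len(idx) < 2:
                continue
            tb = Tensor(theta[idx])
            xb = x[idx] if x is not None else None
            lp = flow.log_prob_tensor(tb, xb, training=True)
            loss = -lp.mean()
            if not np.isfinite(loss.data):
                raise TrainingFailureError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(config.clip_norm)
            ep_loss += float(loss.data)
            n_batches += 1
        hist.train_loss.append(ep_loss / max(n_batches, 1))

        if n_val:
            lp = flow.log_prob_tensor(
                Tensor(theta[val_idx]),
                x[val_idx] if x is not None else None,
                training=False,
            )
            vloss = float(-lp.data.mean())
        else:
            vloss = hist.train_loss[-1]
        hist.val_loss.append(vloss)
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_state = [p.data.copy() for p in params]
            best_bn = _bn_state(flow)
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    for p, s in zip(params, best_state):
        p.data = s
    _restore_bn(flow, best_bn)
    return hist


def _bn_state(flow):
    bns = getattr(flow, "bns", [])
    return [(bn.running_mean.copy(), bn.running_var.copy()) for bn in bns]


def _restore_bn(flow, state):
    for bn, (m, v) in zip(getattr(flow, "bns", []), state):
        bn.running_mean, bn.running_var = m, v
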