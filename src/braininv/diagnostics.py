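"""Posterior quality diagnostics: z-score, shrinkage, correlation, sensitivity.

The interpretive contract: an accurate and reliable fit has z-scores near
zero (posterior centred on the truth) and shrinkage near one (posterior much
narrower than the prior). The sensitivity matrix M, the expected outer
product of posterior-density gradients over posterior draws, has large
eigenvalues along directions the estimated density changes fastest: the
directions the inference is most sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapabilityError, DegeneratePosteriorError, PreconditionError
from .inference import PosteriorResult, PosteriorSamples, PriorSpec

__all__ = [
    "DiagnosticsReport",
    "posterior_zscore",
    "posterior_shrinkage",
    "posterior_correlation",
    "sensitivity_eigs",
    "make_report",
]


@dataclass
class DiagnosticsReport:
    """Per-parameter z and shrinkage, posterior correlation, sensitivity eigs."""

    z: np.ndarray
    s: np.ndarray
    corr: np.ndarray
    sens_eigvals: np.ndarray | None = None
    sens_eigvecs: np.ndarray | None = None
    names: tuple = ()

    def to_dict(self) -> dict:
        out = {
            "names": list(self.names),
            "z": self.z.tolist(),
            "shrinkage": self.s.tolist(),
            "correlation": self.corr.tolist(),
        }
        if self.sens_eigvals is not None:
            out["sensitivity_eigenvalues"] = self.sens_eigvals.tolist()
            out["sensitivity_eigenvectors"] = self.sens_eigvecs.tolist()
        return out


def posterior_zscore(samples: PosteriorSamples | np.ndarray,
                     theta_true: np.ndarray) -> np.ndarray:
    """z = |posterior mean - truth| / posterior SD, elementwise."""
    draws = samples.samples if isinstance(samples, PosteriorSamples) else np.atleast_2d(samples)
    if draws.shape[0] < 2:
        raise PreconditionError("need at least 2 draws")
    sd = draws.std(axis=0)
    if np.any(sd == 0):
        raise DegeneratePosteriorError("zero posterior SD; z-score undefined")
    return np.abs((draws.mean(axis=0) - np.asarray(theta_true, dtype=float)) / sd)


def posterior_shrinkage(samples: PosteriorSamples | np.ndarray,
                        prior: PriorSpec) -> np.ndarray:
    """s = 1 - posterior variance / prior variance, elementwise (s <= 1)."""
    draws = samples.samples if isinstance(samples, PosteriorSamples) else np.atleast_2d(samples)
    return 1.0 - draws.var(axis=0) / prior.variance


def posterior_correlation(samples: PosteriorSamples | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the posterior draws."""
    draws = samples.samples if isinstance(samples, PosteriorSamples) else np.atleast_2d(samples)
    if draws.shape[0] < 3:
        raise PreconditionError("need at least 3 draws")
    if np.any(draws.std(axis=0) == 0):
        k = int(np.flatnonzero(draws.std(axis=0) == 0)[0])
        raise DegeneratePosteriorError(f"constant posterior column {k}")
    corr = np.corrcoef(draws.T)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def sensitivity_eigs(
    est: PosteriorResult,
    x_obs,
    n_mc: int = 1000,
    seed: int = 0,
    finite_differences: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of M = E_post[grad p(theta|x) grad p(theta|x)^T].

    The expectation runs over ``n_mc`` posterior draws. Gradients come from
    the flow's autodiff (grad p = p * grad log p); with
    ``finite_differences=True`` central differences with step 1e-4 x prior
    width are used instead. Density values are normalized by their
    posterior-sample mean before forming M, which stabilizes the scale of an
    otherwise unnormalized quantity. Eigenvalues are returned descending;
    M is symmetric PSD by construction.
    """
    if n_mc < 100:
        raise PreconditionError("n_mc must be at least 100")
    draws = est.sample(x_obs, n_draws=n_mc, seed=seed).samples
    if finite_differences:
        step = 1e-4 * (est.prior.upper - est.prior.lower)
        logp = est.log_prob(draws, x_obs)
        grad_logp = np.empty_like(draws)
        for j in range(draws.shape[1]):
            dp = draws.copy()
            dm = draws.copy()
            dp[:, j] += step[j]
            dm[:, j] -= step[j]
            grad_logp[:, j] = (est.log_prob(dp, x_obs) - est.log_prob(dm, x_obs)) / (2 * step[j])
    else:
        try:
            logp, grad_logp = est.log_prob_grad(draws, x_obs)
        except AttributeError as exc:
            raise CapabilityError(
                "estimator does not expose density gradients; "
                "pass finite_differences=True"
            ) from exc
    p = np.exp(logp - logp.max())
    p = p / p.mean()  # scale stabilization of the unnormalized density
    g = p[:, None] * grad_logp  # grad p = p * grad log p (up to the same scale)
    M = (g[:, :, None] * g[:, None, :]).mean(axis=0)
    M = 0.5 * (M + M.T)
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    return np.clip(eigvals[order], 0.0, None), eigvecs[:, order]


def make_report(
    est: PosteriorResult,
    samples: PosteriorSamples,
    theta_true: np.ndarray,
    x_obs=None,
    n_mc_sensitivity: int = 0,
    seed: int = 0,
) -> DiagnosticsReport:
    """Assemble the full diagnostics report for one recovery."""
    z = posterior_zscore(samples, theta_true)
    s = posterior_shrinkage(samples, est.prior)
    corr = posterior_correlation(samples)
    ev = evec = None
    if n_mc_sensitivity:
        if x_obs is None:
            raise PreconditionError(
                "sensitivity analysis needs the raw observation features"
            )
        ev, evec = sensitivity_eigs(est, x_obs, n_mc=n_mc_sensitivity, seed=seed)
    return DiagnosticsReport(z=z, s=s, corr=corr, sens_eigvals=ev,
                             sens_eigvecs=evec, names=samples.names)
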