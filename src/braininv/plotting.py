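"""Diagnostic figures: posterior marginals and z-score vs shrinkage."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_posterior_panels", "plot_z_shrinkage"]


def plot_posterior_panels(samples, prior, theta_true=None, max_panels=12,
                          fig=None):
    """Histogram each posterior marginal against its uniform prior.

    Parameters mirror the study objects: ``samples`` is a PosteriorSamples,
    ``prior`` a PriorSpec, ``theta_true`` an optional ground-truth vector.
    Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    d = min(samples.samples.shape[1], max_panels)
    ncols = min(d, 4)
    nrows = int(np.ceil(d / ncols))
    if fig is None:
        fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows),
                                 squeeze=False)
    else:
        axes = np.array(fig.get_axes()).reshape(nrows, ncols)
    for j in range(d):
        ax = axes[j // ncols][j % ncols]
        lo, hi = prior.lower[j], prior.upper[j]
        ax.hist(samples.samples[:, j], bins=40, range=(lo, hi), density=True,
                color="tab:red", alpha=0.7, label="posterior")
        ax.hlines(1.0 / (hi - lo), lo, hi, color="tab:blue", label="prior")
        if theta_true is not None:
            ax.axvline(theta_true[j], color="tab:green", lw=2, label="truth")
        name = samples.names[j] if j < len(samples.names) else f"p{j}"
        ax.set_title(name, fontsize=9)
    for j in range(d, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    return fig


def plot_z_shrinkage(report, fig=None):
    """Scatter posterior z-score against shrinkage, one point per parameter.

    The ideal-recovery corner is bottom-right: shrinkage near one (data
    constrain the parameter) and z near zero (posterior centred on truth).
    """
    import matplotlib.pyplot as plt

    if fig is None:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
    else:
        ax = fig.gca()
    ax.scatter(report.s, report.z, c="tab:red", s=25)
    for name, s, z in zip(report.names, report.s, report.z):
        ax.annotate(name, (s, z), fontsize=7, alpha=0.7)
    ax.set_xlim(-0.05, 1.05)
    ax.set_xlabel("posterior shrinkage")
    ax.set_ylabel("posterior z-score")
    fig.tight_layout()
    return fig
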