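"""Optional diagnostic plot exports (requires matplotlib).

Thin rendering helpers for the three standard adequacy views: posterior
predictive density overlay, residuals versus fitted values, and the
autocorrelation stem profile with the |r| = 0.2 adequacy band.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import ACF_FLAG_THRESHOLD, AcfProfile, PPCResult

__all__ = ["plot_ppc_density", "plot_residuals_vs_fitted", "plot_acf_profile"]


def _require_pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError("plot exports require matplotlib") from err
    return plt


def plot_ppc_density(ppc: PPCResult, path) -> None:
    """Observed outcome density over the replicate densities."""
    plt = _require_pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    grid = np.linspace(
        min(ppc.observed_y.min(), ppc.replicated_y.min()),
        max(ppc.observed_y.max(), ppc.replicated_y.max()),
        200,
    )
    from scipy.stats import gaussian_kde

    for rep in ppc.replicated_y:
        ax.plot(grid, gaussian_kde(rep)(grid), color="C0", alpha=0.08, lw=0.8)
    ax.plot(grid, gaussian_kde(ppc.observed_y)(grid), color="black", lw=2)
    ax.set_xlabel("sleep duration (min)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_residuals_vs_fitted(residuals: np.ndarray, fitted: np.ndarray, path) -> None:
    plt = _require_pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(fitted, residuals, s=12, alpha=0.6)
    ax.axhline(0.0, color="gray", lw=1)
    ax.set_xlabel("fitted sleep duration (min)")
    ax.set_ylabel("residual (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_acf_profile(profile: AcfProfile, path) -> None:
    plt = _require_pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    avail = ~np.isnan(profile.values)
    ax.stem(profile.lags[avail], profile.values[avail])
    for y in (ACF_FLAG_THRESHOLD, -ACF_FLAG_THRESHOLD):
        ax.axhline(y, color="gray", ls="--", lw=1)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("autocorrelation")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
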