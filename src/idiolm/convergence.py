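"""MCMC convergence diagnostics: split-chain R-hat and autocorrelation ESS.

R-hat is the split-chain potential scale reduction factor: each chain is
halved, and the ratio of pooled-to-within variance is formed across the
resulting half-chains, so within-chain drift registers as apparent
non-convergence.  ESS discounts the nominal draw count by the integrated
autocorrelation time, estimated with Geyer's initial-monotone-positive-
sequence truncation; with nearly uncorrelated draws it approaches the total
number of retained draws, at which it is capped.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rhat", "ess", "rank_normalize"]


def _as_chains(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected draws shaped (chains, iterations)")
    if x.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    if x.shape[1] < 4:
        raise ValueError("at least 4 draws per chain are required")
    return x


def _split_chains(x: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    h = n // 2
    return np.vstack([x[:, :h], x[:, n - h :]])


def rank_normalize(x: np.ndarray) -> np.ndarray:
    """Map pooled draws to normal scores (fractional ranks -> z-scores)."""
    from scipy.stats import norm, rankdata

    flat = rankdata(x, axis=None)
    z = norm.ppf((flat - 0.375) / (x.size + 0.25))
    return z.reshape(x.shape)


def rhat(draws: np.ndarray, rank_normalized: bool = False) -> float:
    """Split-chain potential scale reduction factor.

    Values near 1 indicate the chains share a stationary distribution; the
    conventional adequacy cut-off is 1.1.  Zero-variance draws are defined
    to have R-hat 1 (a point mass is trivially converged).
    """
    x = _as_chains(draws)
    if rank_normalized:
        x = rank_normalize(x)
    sx = _split_chains(x)
    m, n = sx.shape
    chain_means = sx.mean(axis=1)
    chain_vars = sx.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if _degenerate(w, sx):
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    # below-1 values are estimator noise; report the conservative bound
    return float(max(1.0, np.sqrt(var_plus / w)))


def _degenerate(w: float, sx: np.ndarray) -> bool:
    """True when the within-chain variance is zero up to rounding noise."""
    scale = max(float(np.abs(sx).max(initial=0.0)), 1.0)
    return w <= (1e-12 * scale) ** 2


def _chain_autocov(sx: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariance of each chain via FFT."""
    m, n = sx.shape
    centered = sx - sx.mean(axis=1, keepdims=True)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), nfft, axis=1)[:, :n].real
    return acov / n


def ess(draws: np.ndarray) -> float:
    """Effective sample size of pooled draws from multiple chains.

    Combines within-chain autocorrelations with the between-chain variance
    (so non-mixing chains yield a small ESS even if each chain is white),
    truncates the autocorrelation sum at Geyer's initial positive sequence
    with the monotone adjustment, and caps the result at the total number
    of draws.
    """
    x = _as_chains(draws)
    total = x.size
    sx = _split_chains(x)
    m, n = sx.shape
    acov = _chain_autocov(sx)
    chain_vars = acov[:, 0] * n / (n - 1)
    w = chain_vars.mean()
    if _degenerate(w, sx):
        return float(total)
    b = n * sx.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    if var_plus == 0.0:
        return float(total)

    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (w - mean_acov) / var_plus
    rho[0] = 1.0

    # Geyer initial monotone positive sequence on paired sums
    max_pairs = (n - 1) // 2
    tau = 0.0
    prev_pair = np.inf
    used_any = False
    for k in range(max_pairs + 1):
        t0, t1 = 2 * k, 2 * k + 1
        if t1 >= n:
            pair = rho[t0]
        else:
            pair = rho[t0] + rho[t1]
        if pair < 0.0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        used_any = True
    if not used_any:
        tau = 1.0
    tau -= 1.0  # rho_0 counted twice in the first pair
    tau = max(tau, 1.0 / np.log10(total + 10))  # guard absurd anticorrelation
    return float(min(total, total / tau))
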