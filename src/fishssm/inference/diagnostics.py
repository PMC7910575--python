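"""Convergence diagnostics and posterior summaries.

The Gelman-Rubin potential scale reduction factor (PSRF) compares the
between-chain and within-chain variances:

    W = mean of within-chain variances
    B/n = variance of chain means
    Vhat = (n-1)/n * W + B/n
    R-hat = sqrt(Vhat / W)

Values below 1.1 for every parameter are taken as convergence.  With zero
between-chain variance R-hat = sqrt((n-1)/n) <= 1; chains that are all
constant and identical yield exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampler import PosteriorSamples

__all__ = ["gelman_rubin", "summarize", "home_range_area", "RHAT_THRESHOLD"]

#: Conventional convergence threshold for the PSRF.
RHAT_THRESHOLD = 1.1


def gelman_rubin(samples: PosteriorSamples | np.ndarray) -> pd.Series:
    """Classic per-parameter PSRF from multi-chain draws.

    Accepts a PosteriorSamples or a raw (chain, iteration, parameter)
    array; requires at least 2 chains of at least 10 draws each.
    """
    if isinstance(samples, PosteriorSamples):
        draws = samples.draws
        names = list(samples.param_names)
    else:
        draws = np.asarray(samples, float)
        if draws.ndim == 2:
            draws = draws[:, :, None]
        names = [f"param_{i}" for i in range(draws.shape[2])]
    c, n, p = draws.shape
    if c < 2:
        raise ValueError("Gelman-Rubin requires at least 2 chains")
    if n < 10:
        raise ValueError("Gelman-Rubin requires at least 10 draws per chain")
    means = draws.mean(axis=1)  # (c, p)
    w = draws.var(axis=1, ddof=1).mean(axis=0)  # (p,)
    b_over_n = means.var(axis=0, ddof=1)  # (p,)
    vhat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(vhat / w)
    # Degenerate chains: no within-chain spread.
    rhat = np.where(w == 0, np.where(b_over_n == 0, 1.0, np.inf), rhat)
    return pd.Series(rhat, index=names, name="rhat")


def summarize(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Pooled-chain means and equal-tailed credibility intervals.

    Returns a DataFrame indexed by parameter with columns
    ``mean``, ``lower``, ``upper`` and (when >= 2 chains) ``rhat``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    pooled = samples.pooled()
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(pooled, alpha, axis=0)
    upper = np.quantile(pooled, 1.0 - alpha, axis=0)
    out = pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "lower": lower,
            "upper": upper,
        },
        index=list(samples.param_names),
    )
    if samples.n_chains >= 2 and samples.draws.shape[1] >= 10:
        out["rhat"] = gelman_rubin(samples)
    out.index.name = "parameter"
    return out


def home_range_area(radius: float) -> float:
    """Home-range area pi*radius^2 in km^2 for a radius in metres."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    return float(np.pi * radius**2 * 1e-6)
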