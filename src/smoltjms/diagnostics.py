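"""Convergence diagnostics and posterior interval operators."""

from __future__ import annotations

import math

import numpy as np


def gelman_rubin(draws: np.ndarray) -> float:
    """Split-R-hat potential scale reduction factor.

    ``draws`` has shape ``(n_chains, n_draws)``; each chain is split in half
    so within-chain trends inflate the statistic.  Identical constant chains
    return 1 by convention (zero-variance).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be (n_chains, n_draws)")
    n_chains, n = draws.shape
    if n_chains < 2:
        raise ValueError("R-hat needs at least two chains")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    split = np.concatenate([draws[:, :half], draws[:, n - half:]], axis=0)
    m, n2 = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n2 * chain_means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else math.inf
    var_hat = (n2 - 1) / n2 * W + B / n2
    return float(math.sqrt(var_hat / W))


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the shortest window containing ``mass``.

    Sorted-window algorithm; ties broken by the lowest starting index for
    determinism.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HDI")
    n_inc = int(math.ceil(mass * n))
    widths = x[n_inc - 1:] - x[: n - n_inc + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + n_inc - 1])


def effective_sample_size(draws: np.ndarray) -> float:
    """Crude multi-chain ESS from pooled autocorrelations (Geyer initial
    positive sequence), adequate for Monte-Carlo-error bookkeeping."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = draws.shape
    if n < 4:
        return float(m * n)
    centred = draws - draws.mean(axis=1, keepdims=True)
    var = centred.var(axis=1).mean()
    if var == 0:
        return float(m * n)
    max_lag = min(n - 1, 1000)
    rho_sum = 0.0
    prev = None
    for lag in range(1, max_lag, 2):
        r1 = np.mean([np.dot(c[:-lag], c[lag:]) / n for c in centred]) / var
        r2 = 0.0
        if lag + 1 < n:
            r2 = np.mean([np.dot(c[:-(lag + 1)], c[lag + 1:]) / n
                          for c in centred]) / var
        pair = r1 + r2
        if pair < 0 or (prev is not None and pair > prev):
            break
        rho_sum += pair
        prev = pair
    ess = m * n / (1.0 + 2.0 * rho_sum)
    return float(min(ess, m * n))
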