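"""Posterior summaries: HDI, probability of direction, ROPE, split-Rhat."""

from __future__ import annotations

import numpy as np

__all__ = ["hdi", "prob_direction", "rope", "split_rhat"]


def hdi(draws: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval holding ``mass`` of the draws.

    Empirical smallest-width method on sorted draws; requires >= 100 draws.
    """
    if not 0 < mass < 1:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise ValueError("HDI needs at least 100 draws")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def prob_direction(draws: np.ndarray) -> float:
    """Posterior probability of direction, as a percentage in [50, 100].

    ``100 * max(#neg, #pos) / #draws`` — the share of posterior mass on the
    dominant side of zero.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("prob_direction needs at least 100 draws")
    neg = np.sum(x < 0)
    pos = np.sum(x > 0)
    return float(100.0 * max(neg, pos) / len(x))


def rope(
    draws: np.ndarray,
    rope_range: tuple[float, float],
    hdi_mass: float = 0.89,
) -> float:
    """Fraction of the HDI lying inside the region of practical equivalence.

    Values near 0 indicate an effect clearly outside the negligible band;
    values near 1 an effect indistinguishable from zero.
    """
    lo, hi = rope_range
    if hi < lo:
        raise ValueError("rope_range upper bound below lower bound")
    x = np.asarray(draws, dtype=float).ravel()
    h_lo, h_hi = hdi(x, hdi_mass)
    if h_hi == h_lo:
        return 1.0 if lo <= h_lo <= hi else 0.0
    inside_hdi = x[(x >= h_lo) & (x <= h_hi)]
    return float(np.mean((inside_hdi >= lo) & (inside_hdi <= hi)))


def split_rhat(chains: np.ndarray) -> float:
    """Classic split-chain potential scale reduction statistic.

    ``chains`` has shape (n_chains, n_draws). Each chain is split in half;
    Rhat = sqrt(((n-1)/n W + B/n) / W) over the split halves. Values near 1
    indicate the chains sample the same distribution.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("split_rhat needs >= 2 chains of draws")
    if x.shape[1] < 4:
        raise ValueError("split_rhat needs >= 4 draws per chain")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
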