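"""Driver screening: correlation pruning and the soil principal components."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["prune_correlated", "soil_pca", "PCAResult"]


def prune_correlated(
    drivers: pd.DataFrame,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> list[str]:
    """Iteratively drop one member of every driver pair with |r| > threshold.

    ``priority`` lists drivers from most to least preferred (the ecological
    choice is the caller's); unlisted drivers rank after listed ones in
    column order. The comparison is strict, so a pair at exactly |r| = 0.7
    is retained. Constant drivers are dropped with a warning up front.
    """
    if drivers.shape[1] < 2 or len(drivers) < 3:
        raise ValueError("need >= 2 drivers over >= 3 observations")
    cols = list(drivers.columns)
    constant = [c for c in cols if np.std(drivers[c].to_numpy(dtype=float)) == 0]
    if constant:
        logger.warning("constant drivers dropped before correlation: %s", constant)
    retained = [c for c in cols if c not in constant]
    prio = list(priority or [])
    rank = {c: (prio.index(c) if c in prio else len(prio) + cols.index(c))
            for c in cols}
    while True:
        if len(retained) < 2:
            break
        corr = drivers[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        a, b = retained[i], retained[j]
        drop = a if rank[a] > rank[b] else b
        logger.info("dropping %s (|r|=%.3f with %s)", drop, corr[i, j],
                    a if drop == b else b)
        retained.remove(drop)
    return retained


@dataclass
class PCAResult:
    """Loadings, scores and variance shares of a standardized PCA."""

    loadings: pd.DataFrame        # variables x axes
    scores: pd.DataFrame          # plots x axes
    variance_fraction: pd.Series  # per axis, sums to 1
    selected_axes: list[str]      # axes explaining >= 10% of variance


def soil_pca(table: pd.DataFrame, select_threshold: float = 0.10) -> PCAResult:
    """PCA of the plot-level soil variables (centred, unit variance).

    Axes are ordered by explained variance; those explaining at least
    ``select_threshold`` of it are selected. Each axis is oriented so that
    its largest-|loading| variable loads positively, making loading tables
    reproducible across platforms.
    """
    if len(table) < 4:
        raise ValueError("soil PCA needs >= 4 plots")
    if table.shape[1] < 3:
        raise ValueError("soil PCA needs >= 3 variables")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(table.columns[sd == 0])
        raise ValueError(f"constant soil variables: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    if vals[0] <= 0:
        raise ValueError("degenerate soil table: no positive variance")
    frac = vals / vals.sum()
    # orient: largest-|loading| variable positive on each axis
    for k in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    axes = [f"PC{k + 1}" for k in range(len(vals))]
    loadings = pd.DataFrame(vecs, index=table.columns, columns=axes)
    scores = pd.DataFrame(Z @ vecs, index=table.index, columns=axes)
    variance = pd.Series(frac, index=axes)
    selected = [a for a in axes if variance[a] >= select_threshold]
    return PCAResult(loadings, scores, variance, selected)
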