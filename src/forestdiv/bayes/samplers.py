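"""Univariate slice sampler used inside the Gibbs updates.

Stepping-out slice sampling (Neal 2003): tuning-free apart from an initial
step width, exact for any continuous univariate log-density, and free of the
random-walk rejection autocorrelation that makes Metropolis chains slow to
satisfy tight Rhat gates.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["slice_sample"]


def slice_sample(
    x0: float,
    logf,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """One slice-sampling update of a scalar with log-density ``logf``."""
    f0 = logf(x0)
    if not math.isfinite(f0):
        raise ValueError("slice_sample started outside the support")
    logy = f0 + math.log(rng.random())
    u = rng.random()
    left = x0 - u * w
    right = left + w
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logf(left) > logy:
        left -= w
        j -= 1
    while k > 0 and logf(right) > logy:
        right += w
        k -= 1
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pathological shrinkage; keep the current state
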