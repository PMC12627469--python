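"""Seeded univariate slice sampling (stepping-out + shrinkage).

The hierarchical truncated-normal models and the Bayesian mixed models in
this package are sampled with slice-within-Gibbs updates: each scalar is
updated from its full conditional with Neal's (2003) slice sampler.  The
procedure is derivative-free, has no rejections, adapts automatically to
the local scale of the conditional, and is fully deterministic given a
``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = ["slice_sample"]


def slice_sample(
    logpdf: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    w: float = 1.0,
    lo: float = -math.inf,
    hi: float = math.inf,
    max_steps: int = 50,
) -> float:
    """One slice-sampling update of a scalar with target ``logpdf``.

    ``w`` is the initial bracket width (a scale guess, not a tuning
    requirement), ``lo``/``hi`` optional hard support bounds.  Returns the
    new state; if the current point has zero density the state is returned
    unchanged (callers initialize inside the support).
    """
    f0 = logpdf(x0)
    if not np.isfinite(f0):
        return x0
    log_y = f0 - rng.exponential()

    # stepping out
    u = rng.uniform(0.0, w)
    left = max(x0 - u, lo)
    right = min(left + w, hi)
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and left > lo and logpdf(left) > log_y:
        left = max(left - w, lo)
        j -= 1
    while k > 0 and right < hi and logpdf(right) > log_y:
        right = min(right + w, hi)
        k -= 1

    # shrinkage
    for _ in range(1000):
        x1 = rng.uniform(left, right)
        if logpdf(x1) > log_y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pathological flat slice; keep current state
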