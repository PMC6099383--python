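"""Constant-rate birth-death probability kernels.

Shared by the clade-moments estimators, the rate-shift likelihood and the
simulators.  Everything is parameterized either by (b, d) or by
(r, eps) with r = b - d (net diversification) and eps = d / b (relative
extinction); the two are interchangeable through :func:`bd_from_r_eps`.

Core quantities for a single lineage observed after time ``t``:

* ``survival_prob``   P(at least one extant descendant)
* ``beta``            the geometric parameter of the descendant-count law:
                      conditional on survival, P(N = n) = (1 - beta) beta^(n-1)
* ``log_p1``          log P(exactly one extant descendant)

The critical case b == d is handled by its analytic limit.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

__all__ = [
    "bd_from_r_eps",
    "r_eps_from_bd",
    "beta",
    "alpha",
    "survival_prob",
    "log_p1",
    "clade_richness_loglik",
    "crown_size_cdf",
]

_R_CRITICAL = 1e-9  # below this |r|, use the b == d limit


def bd_from_r_eps(r: float, eps: float) -> Tuple[float, float]:
    """Convert (net diversification, relative extinction) to (b, d)."""
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"relative extinction must lie in [0, 1), got {eps}")
    b = r / (1.0 - eps)
    return b, b * eps


def r_eps_from_bd(b: float, d: float) -> Tuple[float, float]:
    if b <= 0:
        raise ValueError(f"speciation rate must be positive, got {b}")
    if d < 0:
        raise ValueError(f"extinction rate must be nonnegative, got {d}")
    return b - d, d / b


def beta(b: float, d: float, t) -> float:
    """Geometric parameter of the descendant count after time t.

    beta = b (1 - e^{-rt}) / (b - d e^{-rt}); for b == d it tends to
    bt / (1 + bt).
    """
    t = np.asarray(t, dtype=float)
    r = b - d
    if abs(r) < _R_CRITICAL * max(b, 1.0):
        return b * t / (1.0 + b * t)
    ert = np.exp(-r * t)
    return b * (1.0 - ert) / (b - d * ert)


def alpha(b: float, d: float, t) -> float:
    """Extinction probability of a single lineage after time t (= eps * beta)."""
    if b == 0:
        return 1.0 - np.exp(-d * np.asarray(t, dtype=float))
    return (d / b) * beta(b, d, t)


def survival_prob(b: float, d: float, t) -> float:
    return 1.0 - alpha(b, d, t)


def log_p1(b: float, d: float, t):
    """log P(exactly one extant descendant after time t).

    p1(t) = r^2 e^{-rt} / (b - d e^{-rt})^2, reducing to e^{-bt} for d = 0
    and to 1/(1+bt)^2 for b = d.
    """
    t = np.asarray(t, dtype=float)
    r = b - d
    if abs(r) < _R_CRITICAL * max(b, 1.0):
        return -2.0 * np.log1p(b * t)
    ert = np.exp(-r * t)
    return math.log(r**2) - r * t - 2.0 * np.log(b - d * ert)


def clade_richness_loglik(n, t, b: float, d: float):
    """log P(N(t) = n | N(0) = 1, survival to the present).

    The descendant count of a surviving lineage is geometric:
    P(n) = (1 - beta) beta^(n-1).
    """
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("clade richness must be >= 1")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("stem age must be positive")
    if b <= 0 or d < 0:
        raise ValueError(f"invalid rates b={b}, d={d}")
    be = beta(b, d, t)
    return np.log1p(-be) + (n - 1) * np.log(be)


def crown_size_cdf(n, r: float, eps: float, t: float, conditioning: str = "clade"):
    """CDF of the extant size of a crown clade of age t.

    The clade starts as two lineages at the crown node.  With
    ``conditioning="clade"`` each lineage evolves unconditioned and the total
    is conditioned on the clade surviving (N >= 1); with
    ``conditioning="both"`` each basal lineage is required to survive, giving
    the negative-binomial law P(N = n) = (n - 1)(1 - beta)^2 beta^(n-2).

    Accepts non-integer ``n`` (continuous extension of the survival function),
    which is convenient for quantile inversion.
    """
    if r <= 0:
        raise ValueError(f"net diversification must be positive, got {r}")
    b, d = bd_from_r_eps(r, eps)
    be = float(beta(b, d, t))
    al = eps * be
    n = np.asarray(n, dtype=float)
    if conditioning == "both":
        if np.any(n < 2):
            raise ValueError("crown clade conditioned on both lineages has N >= 2")
        tail = be ** (n - 1) * (1.0 + (n - 1) * (1.0 - be))
        return 1.0 - tail
    if conditioning != "clade":
        raise ValueError(f"unknown conditioning {conditioning!r}")
    if np.any(n < 1):
        raise ValueError("clade size must be >= 1")
    # P(N > n) for the sum of two unconditioned lineages, n >= 1:
    tail = 2 * al * (1 - al) * be**n + (1 - al) ** 2 * be ** (n - 1) * (
        1.0 + (n - 1) * (1.0 - be)
    )
    return 1.0 - tail / (1.0 - al**2)
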