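"""Method-of-moments clade diversification and expected-richness envelopes.

Point estimators (Magallon & Sanderson style) recover the net
diversification rate r = b - d of a clade from its standing richness n, its
age t and an assumed relative extinction eps = d/b:

* stem age:   r = ln(n (1 - eps) + eps) / t
* crown age:  the survival-conditioned crown estimator, which reduces to
              ln(n/2) / t at eps = 0.

The richness envelope inverts the question: given r, eps and an age, which
extant clade sizes are compatible at a 95% level?  Bounds are integer
quantiles of the birth-death clade-size distribution (two basal lineages
for crown ages, one for stem ages), conditioned on clade survival by
default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .bd import beta, bd_from_r_eps, crown_size_cdf
from .trees import TimeTree

__all__ = [
    "ms_rate_stem",
    "ms_rate_crown",
    "expected_richness_ci",
    "RichnessEnvelope",
    "richness_envelope",
    "classify_clade",
    "CladeEstimate",
    "clade_rates",
    "TraitGroup",
    "pool_by_trait",
    "compare_groups",
    "scale_richness",
]


def _check_common(t: float, eps: float) -> None:
    if t <= 0:
        raise ValueError(f"clade age must be positive, got {t}")
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"relative extinction must lie in [0, 1), got {eps}")


def ms_rate_stem(n: float, t: float, eps: float = 0.0) -> float:
    """Stem-age method-of-moments net diversification, ln(n(1-eps)+eps)/t."""
    _check_common(t, eps)
    if n < 1:
        raise ValueError(f"stem clade richness must be >= 1, got {n}")
    return math.log(n * (1.0 - eps) + eps) / t


def ms_rate_crown(n: float, t: float, eps: float = 0.0) -> float:
    """Crown-age method-of-moments net diversification.

    Survival-conditioned crown estimator:

        r = (1/t) [ ln( n(1-eps^2)/2 + 2 eps
                        + (1-eps)/2 sqrt(n (n eps^2 - 8 eps + 2 n eps + n)
                                          + 4 eps^2) ) - ln 2 ]

    which collapses to ln(n/2)/t when eps = 0.
    """
    _check_common(t, eps)
    if n < 2:
        raise ValueError(f"crown clade richness must be >= 2, got {n}")
    inner = (
        0.5 * n * (1.0 - eps**2)
        + 2.0 * eps
        + 0.5
        * (1.0 - eps)
        * math.sqrt(n * (n * eps**2 - 8.0 * eps + 2.0 * n * eps + n) + 4.0 * eps**2)
    )
    return (math.log(inner) - math.log(2.0)) / t


def _stem_size_cdf(n, r: float, eps: float, t: float):
    """CDF of a surviving stem clade's extant size (geometric law)."""
    b, d = bd_from_r_eps(r, eps)
    be = float(beta(b, d, t))
    return 1.0 - be ** np.asarray(n, dtype=float)


def expected_richness_ci(
    r: float,
    eps: float,
    t: float,
    age_type: str = "crown",
    level: float = 0.95,
    conditioning: str = "clade",
) -> Tuple[int, int]:
    """Integer bounds on extant clade size compatible with (r, eps) at age t.

    Lower bound: the minimal clade size (2 for crown, 1 for stem) or the
    floor of the lower quantile, whichever is larger.  Upper bound: the
    smallest n whose cumulative probability reaches the upper quantile.

    ``conditioning`` applies to crown clades: "clade" (default) conditions
    the two-lineage total on at least one survivor, "both" requires both
    basal lineages to survive.
    """
    if r <= 0:
        raise ValueError(f"richness envelope needs r > 0, got {r}")
    _check_common(t, eps)
    q_lo = (1.0 - level) / 2.0
    q_hi = 1.0 - q_lo
    if age_type == "crown":
        n_min = 2 if conditioning == "both" else 1
        cdf = lambda x: crown_size_cdf(x, r, eps, t, conditioning=conditioning)
        floor_size = 2
    elif age_type == "stem":
        n_min = 1
        cdf = lambda x: _stem_size_cdf(x, r, eps, t)
        floor_size = 1
    else:
        raise ValueError(f"age_type must be 'crown' or 'stem', got {age_type!r}")

    def invert(q: float) -> float:
        if cdf(n_min) >= q:
            return float(n_min)
        hi = float(n_min + 1)
        while cdf(hi) < q:
            hi *= 4.0
            if hi > 1e12:  # pragma: no cover - guards runaway parameters
                raise ArithmeticError("quantile search exceeded 1e12 species")
        return brentq(lambda x: cdf(x) - q, n_min, hi)

    lower = max(floor_size, int(math.floor(invert(q_lo))))
    upper = int(math.ceil(invert(q_hi)))
    while cdf(upper) < q_hi:  # integer CDF may sit just below the cutoff
        upper += 1
    return lower, upper


@dataclass
class RichnessEnvelope:
    """Expected-richness interval as a function of clade age."""

    r: float
    eps: float
    age_type: str
    ages: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    conditioning: str = "clade"

    def at(self, t: float) -> Tuple[int, int]:
        """Exact bounds at age t (no grid interpolation)."""
        return expected_richness_ci(
            self.r, self.eps, t, self.age_type, self.level, self.conditioning
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_myr": self.ages, "lower": self.lower, "upper": self.upper}
        )


def richness_envelope(
    r: float,
    eps: float,
    ages: Sequence[float],
    age_type: str = "crown",
    level: float = 0.95,
    conditioning: str = "clade",
) -> RichnessEnvelope:
    ages = np.asarray(ages, dtype=float)
    lower = np.empty(len(ages), dtype=int)
    upper = np.empty(len(ages), dtype=int)
    for i, t in enumerate(ages):
        lower[i], upper[i] = expected_richness_ci(r, eps, t, age_type, level, conditioning)
    return RichnessEnvelope(r, eps, age_type, ages, lower, upper, level, conditioning)


def classify_clade(n: int, t: float, envelope: RichnessEnvelope) -> str:
    """Compare a clade's richness against the envelope at its age.

    Returns "below", "within" (closed interval) or "above".
    """
    lo, hi = envelope.at(t)
    if n < lo:
        return "below"
    if n > hi:
        return "above"
    return "within"


@dataclass
class CladeEstimate:
    clade: str
    age_type: str
    age: float
    richness: float
    eps: float
    rate: float


def clade_rates(
    trees: Sequence[TimeTree],
    clades: Mapping[str, Sequence[str]],
    richness: Mapping[str, float],
    eps: float,
    age_type: str = "crown",
) -> pd.DataFrame:
    """Per-clade net diversification across bootstrap trees.

    For each tree the clade age is the MRCA age (crown) or its parent's age
    (stem); richness is fixed.  Returns one row per clade with the mean and
    min-max range across trees, plus per-tree estimates in long form columns.
    """
    rows = []
    for clade_id, tip_set in clades.items():
        n = richness[clade_id]
        estimates, ages = [], []
        for tree in trees:
            node = tree.mrca(tip_set)
            if age_type == "crown":
                t = tree.age(node)
                est = ms_rate_crown(n, t, eps)
            else:
                if node.parent is None:
                    t, est = math.nan, math.nan
                else:
                    t = tree.age(node.parent)
                    est = ms_rate_stem(n, t, eps)
            ages.append(t)
            estimates.append(est)
        est = np.asarray(estimates, dtype=float)
        ages = np.asarray(ages, dtype=float)
        rows.append(
            {
                "clade": clade_id,
                "age_type": age_type,
                "richness": n,
                "eps": eps,
                "age_mean": float(np.nanmean(ages)),
                "age_min": float(np.nanmin(ages)),
                "age_max": float(np.nanmax(ages)),
                "r_mean": float(np.nanmean(est)),
                "r_min": float(np.nanmin(est)),
                "r_max": float(np.nanmax(est)),
                "n_trees": len(trees),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TraitGroup:
    """A maximal monophyletic set of tips sharing one trait category."""

    group_id: str
    category: str
    tips: frozenset


def pool_by_trait(tree: TimeTree, traits: Mapping[str, str]) -> List[TraitGroup]:
    """Partition tips into the most inclusive monophyletic same-trait groups.

    Every tip must be categorized.  Paraphyletic trait categories therefore
    split into several groups, one per maximal uniform clade.
    """
    missing = [t for t in tree.tip_labels if t not in traits]
    if missing:
        raise KeyError(f"tips without a trait category: {', '.join(sorted(missing))}")
    uniform: Dict[object, Optional[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            uniform[node] = traits[node.label]
        else:
            cats = {uniform[c] for c in node.children}
            uniform[node] = cats.pop() if len(cats) == 1 and None not in cats else None
    groups: List[TraitGroup] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        cat = uniform[node]
        if cat is not None:
            tips = tree.bipartition(node)
            groups.append(TraitGroup(f"{cat}_{len(groups)}", cat, tips))
        else:
            stack.extend(node.children)
    groups.sort(key=lambda g: sorted(g.tips)[0])
    return [
        TraitGroup(f"{g.category}_{i+1}", g.category, g.tips)
        for i, g in enumerate(groups)
    ]


def compare_groups(samples: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise mean rate ratios with Tukey-HSD adjusted p-values.

    Ratio convention: row ``(a, b)`` reports mean(a) / mean(b).  Groups with
    fewer than two samples are excluded with a warning.
    """
    kept = {k: np.asarray(v, dtype=float) for k, v in samples.items() if len(v) >= 2}
    dropped = sorted(set(samples) - set(kept))
    if dropped:
        warnings.warn(
            f"excluding degenerate group(s) with < 2 samples: {', '.join(dropped)}",
            stacklevel=2,
        )
    if len(kept) < 2:
        raise ValueError("need at least two groups with >= 2 samples each")
    names = list(kept)
    res = stats.tukey_hsd(*[kept[k] for k in names])
    rows = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": float(np.mean(kept[a])),
                    "mean_b": float(np.mean(kept[b])),
                    "ratio": float(np.mean(kept[a]) / np.mean(kept[b])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def scale_richness(
    clade_counts: Mapping[str, float], n_total: float
) -> Dict[str, float]:
    """Proportionally rescale per-clade species counts to a total-richness scenario."""
    total = float(sum(clade_counts.values()))
    if total <= 0 or n_total <= 0:
        raise ValueError("richness totals must be positive")
    factor = n_total / total
    return {k: v * factor for k, v in clade_counts.items()}
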