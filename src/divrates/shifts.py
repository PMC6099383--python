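"""Stepwise AICc detection of diversification-rate shifts (Medusa-style).

The tree is a time-calibrated backbone whose tips may carry unresolved
species richness.  A model is a partition of branches into rate classes,
each with its own constant (b, d).  The per-class log-likelihood combines

* a reconstructed-process (Nee-type) term for the resolved backbone: each
  branch from age ``t_top`` down to ``t_bot`` contributes
  ``log p1(t_top) - log p1(t_bot)`` with ``p1`` the probability of leaving
  exactly one reconstructed lineage, and each internal split contributes
  ``log b``;
* a richness term for each unresolved tip: the survival-conditioned
  geometric probability of its extant species count given its stem age.

Because a class's likelihood depends only on its own parameters, classes
are fitted independently.  The root's split is treated as given (crown-age
conditioning); optionally the likelihood is further conditioned on the
survival of the two root lineages.

The stepwise search starts from a single class and greedily adds one shift
at a time, trying every branch with both stem placement (branch + subtree)
and node placement (subtree only); a shift is kept only when it improves
AICc by more than a user-supplied threshold.  Candidates are ranked with a
cheap fit of the new class alone, and the top few are refitted in full
before the acceptance decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from . import bd
from .bd import clade_richness_loglik  # re-exported; part of the public surface
from .trees import Node, TimeTree

__all__ = [
    "aicc",
    "default_threshold",
    "backbone_loglik",
    "clade_richness_loglik",
    "fit_class_parameters",
    "ShiftModel",
    "ShiftResults",
    "stepwise_search",
    "summarize_shifts",
]

EPS_MAX = 0.999


def _expit(x: float) -> float:
    # overflow-safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-min(x, 700.0)))
    z = math.exp(max(x, -700.0))
    return z / (1.0 + z)
# Rates are searched on a bounded log scale.  The upper bounds (10 events
# per Myr per lineage for both net diversification r and speciation b, far
# above the fastest reported radiations) matter: the reconstructed-process
# density at near-coincident node times is unbounded in raw turnover, so a
# near-zero-duration cherry could otherwise drive a degenerate shift class
# to arbitrarily high rates (directly through r, or through eps -> 1 at
# fixed r) and an arbitrarily large likelihood gain.
LOG_R_MIN, LOG_R_MAX = math.log(1e-7), math.log(10.0)
B_MAX = 10.0


def _eps_cap(r: float) -> float:
    """Largest relative extinction keeping the speciation rate below B_MAX."""
    return min(EPS_MAX, max(1.0 - r / B_MAX, 0.0))
DEFAULT_THRESHOLDS = {234: 6.7, 45: 2.3}


def aicc(loglik: float, k: int, n_obs: int) -> float:
    """Small-sample-corrected AIC: -2 logL + 2k + 2k(k+1)/(n_obs - k - 1)."""
    if n_obs <= k + 1:
        raise ValueError(f"AICc undefined: n_obs={n_obs} must exceed k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def default_threshold(n_tips: int) -> float:
    """Improvement thresholds keyed by tree size (no interpolation)."""
    try:
        return DEFAULT_THRESHOLDS[n_tips]
    except KeyError:
        raise ValueError(
            f"no default AICc threshold for a {n_tips}-tip tree; supply one explicitly"
        ) from None


# --------------------------------------------------------------------------- #
# flattened tree                                                              #
# --------------------------------------------------------------------------- #


class _FlatTree:
    """Array view of a TimeTree for fast likelihood evaluation."""

    def __init__(self, tree: TimeTree, richness: Optional[Mapping[str, float]] = None):
        nodes = tree.nodes  # preorder; root first
        self.tree = tree
        self.nodes = nodes
        index = {id(n): i for i, n in enumerate(nodes)}
        M = len(nodes)
        self.parent = np.array(
            [-1 if n.parent is None else index[id(n.parent)] for n in nodes], dtype=int
        )
        self.age = np.array([tree.age(n) for n in nodes])
        self.is_tip = np.array([n.is_tip for n in nodes])
        self.nchildren = np.array([len(n.children) for n in nodes], dtype=int)
        rich = np.ones(M)
        if richness is not None:
            for i, n in enumerate(nodes):
                if n.is_tip:
                    if n.label not in richness:
                        raise KeyError(f"no richness entry for tip {n.label!r}")
                    rich[i] = float(richness[n.label])
        if np.any(rich[self.is_tip] < 1):
            raise ValueError("tip richness must be >= 1")
        self.richness = rich
        bips = tree.bipartitions()
        self.bipartition = [bips[n] for n in nodes]
        # branch geometry (undefined for the root, masked everywhere below)
        self.t_top = np.where(self.parent >= 0, self.age[self.parent], np.nan)
        self.t_bot = self.age
        self.stem_span = self.t_top - self.t_bot
        # split multiplicities: root's split is conditioned on, not modeled
        ev = np.where(self.is_tip, 0, self.nchildren - 1)
        ev[0] = max(self.nchildren[0] - 2, 0)
        self.n_events = ev
        self.n_internal = int(np.sum(~self.is_tip))
        self.n_tips = int(np.sum(self.is_tip))
        self.root_age = self.age[0]
        self.preorder_idx = np.arange(M)  # nodes are already stored in preorder

    @property
    def n_obs(self) -> int:
        """Likelihood contributions: backbone internal nodes + unresolved tips."""
        return self.n_internal + self.n_tips


@dataclass(frozen=True)
class _Shift:
    node: int
    placement: str  # "stem" | "node"


def _assignment(flat: _FlatTree, shifts: Sequence[_Shift]) -> Tuple[np.ndarray, np.ndarray]:
    """Class of each branch and of each node under the innermost-shift rule.

    A stem shift at v recolors the branch above v and everything below; a
    node shift recolors v's split and everything below but leaves v's own
    branch with its parent.  Class 0 is the root (background) class; shift
    i defines class i + 1.
    """
    M = len(flat.nodes)
    stem_at = {}
    node_at = {}
    for ci, sh in enumerate(shifts):
        if sh.placement == "stem":
            stem_at[sh.node] = ci + 1
        elif sh.placement == "node":
            node_at[sh.node] = ci + 1
        else:
            raise ValueError(f"unknown placement {sh.placement!r}")
    inherit = np.zeros(M, dtype=int)
    branch_class = np.zeros(M, dtype=int)
    for i in range(M):  # preorder guarantees parents precede children
        p = flat.parent[i]
        if p < 0:
            inherit[i] = node_at.get(i, 0)
            continue
        own = stem_at.get(i)
        branch_class[i] = own if own is not None else inherit[p]
        inherit[i] = own if own is not None else node_at.get(i, inherit[p])
    return branch_class, inherit  # inherit doubles as the node-class array


# --------------------------------------------------------------------------- #
# per-class likelihood                                                        #
# --------------------------------------------------------------------------- #


class _ClassData:
    """Precomputed sufficient statistics of one rate class.

    The class log-likelihood decomposes into terms linear in
    ``log(b - d e^{-r t})`` and ``log(1 - e^{-r t})`` over a fixed set of
    node ages, so the per-evaluation work collapses to one ``exp`` and two
    ``log`` calls over a single concatenated age vector with constant
    coefficient vectors.
    """

    __slots__ = (
        "t_all", "c_logD", "c_log1mu", "c_logb", "c_logr", "c_t",
        "n_events", "root_cond", "root_age", "n_branches", "t_max", "n_total",
    )

    def __init__(
        self,
        t_top_int: np.ndarray,
        t_bot_int: np.ndarray,
        t_stem_tip: np.ndarray,
        n_tip: np.ndarray,
        n_events: int,
        root_cond: bool,
        root_age: float,
    ):
        self.n_events = n_events
        self.root_cond = root_cond
        self.root_age = root_age
        self.n_branches = len(t_top_int) + len(t_stem_tip)
        cond = [root_age] if root_cond else []
        self.t_all = np.concatenate([t_top_int, t_bot_int, t_stem_tip, cond])
        self.c_logD = np.concatenate(
            [
                -2.0 * np.ones(len(t_top_int)),
                +2.0 * np.ones(len(t_bot_int)),
                -(n_tip + 1.0),
                [2.0] if root_cond else [],
            ]
        )
        self.c_log1mu = np.concatenate(
            [
                np.zeros(len(t_top_int) + len(t_bot_int)),
                n_tip - 1.0,
                [0.0] if root_cond else [],
            ]
        )
        # coefficients of log b, log r, and -r
        self.c_logb = float(n_events + np.sum(n_tip - 1.0))
        self.c_logr = 2.0 * len(t_stem_tip) - (2.0 if root_cond else 0.0)
        self.c_t = float(np.sum(t_top_int) - np.sum(t_bot_int) + np.sum(t_stem_tip))
        self.t_max = float(np.max(self.t_all)) if len(self.t_all) else 1e-6
        self.n_total = float(np.sum(n_tip)) if len(n_tip) else 2.0


def _class_data(
    flat: _FlatTree,
    branch_class: np.ndarray,
    node_class: np.ndarray,
    c: int,
    condition_root: bool,
) -> _ClassData:
    in_class = branch_class == c
    internal = in_class & ~flat.is_tip
    pendant = in_class & flat.is_tip
    internal[0] = False  # the root has no branch
    pendant[0] = False
    n_events = int(np.sum(flat.n_events[node_class == c]))
    return _ClassData(
        t_top_int=flat.t_top[internal],
        t_bot_int=flat.t_bot[internal],
        t_stem_tip=flat.stem_span[pendant],
        n_tip=flat.richness[pendant],
        n_events=n_events,
        root_cond=condition_root and c == 0,
        root_age=flat.root_age,
    )


def _class_loglik(r: float, eps: float, data: _ClassData) -> float:
    """Fused class log-likelihood in (r, eps).

    With u = e^{-rt} and D = b - d u:

    * internal branch (t_top, t_bot): log p1(t_top) - log p1(t_bot)
      = -r (t_top - t_bot) - 2 log D(t_top) + 2 log D(t_bot);
    * unresolved tip (stem t, richness n): the UNconditioned clade-size
      probability log[P_s (1-beta) beta^(n-1)]
      = 2 log r - r t - (n+1) log D + (n-1)(log b + log(1-u))
      (the survival factor P_s must stay: dropping it spuriously favors
      high-extinction regimes; at n = 1 the term is exactly log p1);
    * each split: + log b;  root-survival conditioning: -2 log(r / D(t_root)).
    """
    if r <= 0 or not 0.0 <= eps < 1.0:
        return -np.inf
    b = r / (1.0 - eps)
    d = b * eps
    u = np.exp(-r * data.t_all)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(data.c_logD @ np.log(b - d * u))
        ll += float(data.c_log1mu @ np.log1p(-np.minimum(u, 1.0 - 1e-300)))
    ll += data.c_logb * math.log(b) + data.c_logr * math.log(r) - r * data.c_t
    return ll if np.isfinite(ll) else -np.inf


def _mom_r0(data: _ClassData, eps0: float) -> float:
    n_tot = max(data.n_total, 2.0)
    t0 = max(data.t_max, 1e-6)
    return max(math.log(n_tot * (1.0 - eps0) + eps0) / t0, 1e-5)


@dataclass
class RateClass:
    """Fitted (b, d) of one rate class."""

    class_id: int
    b: float
    d: float
    loglik: float
    converged: bool = True
    n_branches: int = 0

    @property
    def r(self) -> float:
        return self.b - self.d

    @property
    def eps(self) -> float:
        return self.d / self.b if self.b > 0 else math.nan

    @property
    def tau(self) -> float:
        return self.b + self.d


def _fit_class(
    data: _ClassData,
    class_id: int,
    n_starts: int = 5,
    seed: int = 0,
    maxfev: int = 400,
) -> RateClass:
    """Maximize the class likelihood over (log r, logit eps).

    Multi-start: eps in {0.05, 0.5, 0.9} with a method-of-moments r
    initializer, plus seeded jitters; a pure-birth 1-D refit is attempted
    whenever the fitted eps collapses to the lower bound.
    """

    def neg(z: np.ndarray) -> float:
        x = min(max(z[0], LOG_R_MIN), LOG_R_MAX)
        r = math.exp(x)
        eps = _eps_cap(r) * _expit(z[1])
        return -_class_loglik(r, eps, data)

    eps_grid = [0.5, 0.05, 0.9][: max(1, min(3, n_starts))]
    starts = [
        np.array([math.log(_mom_r0(data, e)), math.log(e / (EPS_MAX - e))])
        for e in eps_grid
    ]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(starts[0] + rng.normal(scale=[0.7, 1.5]))
    quick = n_starts == 1  # candidate-scan mode: looser tolerances
    best = None
    for z0 in starts:
        res = minimize(
            neg, z0, method="Nelder-Mead",
            options=(
                {"maxfev": min(maxfev, 150), "xatol": 1e-3, "fatol": 1e-6}
                if quick
                else {"maxfev": maxfev, "xatol": 1e-6, "fatol": 1e-9}
            ),
        )
        if best is None or res.fun < best.fun:
            best = res
    r = math.exp(min(max(best.x[0], LOG_R_MIN), LOG_R_MAX))
    eps = _eps_cap(r) * _expit(best.x[1])
    ll = -best.fun
    if eps < 1e-3 and not quick:  # pure-birth fallback along the eps = 0 edge
        res0 = minimize_scalar(
            lambda x: -_class_loglik(math.exp(x), 0.0, data),
            bounds=(LOG_R_MIN, LOG_R_MAX),
            method="bounded",
        )
        if -res0.fun >= ll - 1e-9:
            r, eps, ll = math.exp(res0.x), 0.0, -res0.fun
    b = r / (1.0 - eps)
    return RateClass(
        class_id=class_id,
        b=b,
        d=b * eps,
        loglik=ll,
        converged=bool(np.isfinite(ll)),
        n_branches=data.n_branches,
    )


# --------------------------------------------------------------------------- #
# public single-piece likelihoods                                             #
# --------------------------------------------------------------------------- #


def backbone_loglik(
    tree: TimeTree, b: float, d: float, condition_on_survival: bool = False
) -> float:
    """Single-class reconstructed-process log-likelihood of a resolved tree.

    Each tip counts one extant species.  For d = 0 this is the Yule
    log-likelihood (N - 2) ln b - b * (total branch length) given the crown
    age.
    """
    if b <= 0:
        raise ValueError(f"speciation rate must be positive, got {b}")
    flat = _FlatTree(tree)
    branch_class, node_class = _assignment(flat, [])
    data = _class_data(flat, branch_class, node_class, 0, condition_on_survival)
    r, eps = bd.r_eps_from_bd(b, d)
    return _class_loglik(r, eps, data)


def fit_class_parameters(
    tree: TimeTree,
    richness: Optional[Mapping[str, float]] = None,
    condition_on_survival: bool = True,
    n_starts: int = 5,
    seed: int = 0,
) -> RateClass:
    """Fit a single (b, d) pair to the whole tree plus tip richness."""
    flat = _FlatTree(tree, richness)
    branch_class, node_class = _assignment(flat, [])
    data = _class_data(flat, branch_class, node_class, 0, condition_on_survival)
    return _fit_class(data, 0, n_starts=n_starts, seed=seed)


# --------------------------------------------------------------------------- #
# the model                                                                   #
# --------------------------------------------------------------------------- #


class ShiftModel:
    """Birth-death rate-shift model on a time tree with unresolved tips.

    Parameters
    ----------
    tree : TimeTree
        Time-calibrated tree (ages in Ma / branch lengths in Myr).
    richness : mapping tip label -> extant species count, optional
        Missing mapping means every tip is a single species.
    condition_on_survival : bool
        Condition the background class on survival of the two root lineages.
    """

    def __init__(
        self,
        tree: TimeTree,
        richness: Optional[Mapping[str, float]] = None,
        condition_on_survival: bool = True,
    ):
        self.tree = tree
        self.richness = richness
        self.condition_on_survival = condition_on_survival
        self._flat = _FlatTree(tree, richness)

    @property
    def n_obs(self) -> int:
        return self._flat.n_obs

    def _k(self, n_classes: int) -> int:
        # 2 rate parameters per class plus one location per shift
        return 3 * n_classes - 1

    def _fit_structure(
        self,
        shifts: List[_Shift],
        n_starts: int,
        seed: int,
        refit_only: Optional[set] = None,
        known: Optional[Dict[int, RateClass]] = None,
        maxfev: int = 400,
    ) -> Optional[Tuple[List[RateClass], float, float]]:
        """Fit (or partially refit) all classes of a shift structure.

        Returns (classes, loglik, aicc) or None when some class owns no
        branch (an invalid structure).
        """
        flat = self._flat
        branch_class, node_class = _assignment(flat, shifts)
        n_classes = len(shifts) + 1
        counts = np.bincount(branch_class[1:], minlength=n_classes)
        if np.any(counts == 0):
            return None
        classes: List[RateClass] = []
        total = 0.0
        for c in range(n_classes):
            data = _class_data(flat, branch_class, node_class, c, self.condition_on_survival)
            if known is not None and refit_only is not None and c not in refit_only:
                prev = known[c]
                ll = _class_loglik(prev.r, prev.eps, data)
                rc = RateClass(c, prev.b, prev.d, ll, prev.converged, data.n_branches)
            else:
                rc = _fit_class(data, c, n_starts=n_starts, seed=seed + c, maxfev=maxfev)
            if not np.isfinite(rc.loglik):
                return None
            classes.append(rc)
            total += rc.loglik
        k = self._k(n_classes)
        if self.n_obs <= k + 1:
            return None  # too rich for the data; AICc undefined
        return classes, total, aicc(total, k, self.n_obs)

    def _candidates(self, shifts: List[_Shift]) -> List[_Shift]:
        # Stem placement is eligible on every non-root branch (including
        # single-species tips); node placement only on internal branches.
        taken = {(s.node, s.placement) for s in shifts}
        out = []
        for i in range(1, len(self._flat.nodes)):
            if "stem" in self._placements and (i, "stem") not in taken:
                out.append(_Shift(i, "stem"))
            if (
                "node" in self._placements
                and not self._flat.is_tip[i]
                and (i, "node") not in taken
            ):
                out.append(_Shift(i, "node"))
        return out

    def fit(
        self,
        threshold: Optional[float] = None,
        placements: Sequence[str] = ("stem", "node"),
        max_shifts: int = 20,
        n_starts: int = 5,
        seed: int = 0,
        n_refit_candidates: int = 5,
    ) -> "ShiftResults":
        """Run the stepwise search and return the accepted model.

        ``threshold`` is the AICc improvement required to keep a shift; when
        omitted it is looked up from the tree size (234 -> 6.7, 45 -> 2.3).
        """
        if threshold is None:
            threshold = default_threshold(self._flat.n_tips)
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        self._placements = tuple(placements)
        flat = self._flat

        shifts: List[_Shift] = []
        fitted = self._fit_structure(shifts, n_starts, seed)
        assert fitted is not None
        classes, loglik, current_aicc = fitted
        step_log = [
            {"step": 0, "shifts": 0, "loglik": loglik, "aicc": current_aicc, "accepted": True}
        ]

        while len(shifts) < max_shifts:
            known = {rc.class_id: rc for rc in classes}
            scored = []
            for cand in self._candidates(shifts):
                trial = shifts + [cand]
                new_c = len(trial)
                res = self._fit_structure(
                    trial,
                    n_starts=1,
                    seed=seed,
                    refit_only={new_c},
                    known=known,
                    maxfev=200,
                )
                if res is None:
                    continue
                _, _, cand_aicc = res
                scored.append((cand_aicc, flat.t_top[cand.node], cand))
            if not scored:
                break
            scored.sort(
                key=lambda s: (
                    round(s[0] / 1e-6) * 1e-6,
                    -s[1],  # deeper (older) branch wins ties
                    tuple(sorted(flat.bipartition[s[2].node])),
                )
            )
            best_full = None
            for _, _, cand in scored[:n_refit_candidates]:
                trial = shifts + [cand]
                res = self._fit_structure(
                    trial,
                    n_starts=n_starts,
                    seed=seed,
                    refit_only={len(trial)} | self._affected(shifts, cand),
                    known=known,
                )
                if res is None:
                    continue
                cls, ll, a = res
                key = (
                    round(a / 1e-6) * 1e-6,
                    -flat.t_top[cand.node],
                    tuple(sorted(flat.bipartition[cand.node])),
                )
                if best_full is None or key < best_full[0]:
                    best_full = (key, cand, cls, ll, a)
            if best_full is None:
                break
            _, cand, cls, ll, a = best_full
            accepted = current_aicc - a > threshold
            step_log.append(
                {
                    "step": len(step_log),
                    "shifts": len(shifts) + 1,
                    "loglik": ll,
                    "aicc": a,
                    "accepted": accepted,
                }
            )
            if not accepted:
                break
            shifts.append(cand)
            classes, loglik, current_aicc = cls, ll, a

        return ShiftResults(self, shifts, classes, loglik, current_aicc, step_log)

    def _affected(self, shifts: List[_Shift], cand: _Shift) -> set:
        """Class ids that lose branches to a candidate shift (need refitting)."""
        flat = self._flat
        branch_class, _ = _assignment(flat, shifts)
        sub = self._subtree_mask(cand.node)
        if cand.placement == "node":
            sub = sub.copy()
            sub[cand.node] = False
        return set(np.unique(branch_class[sub]).tolist())

    def _subtree_mask(self, node: int) -> np.ndarray:
        flat = self._flat
        mask = np.zeros(len(flat.nodes), dtype=bool)
        mask[node] = True
        for i in range(node + 1, len(flat.nodes)):
            if mask[flat.parent[i]]:
                mask[i] = True
        return mask


class ShiftResults:
    """Accepted shift structure with per-class rates and fit diagnostics."""

    def __init__(
        self,
        model: ShiftModel,
        shifts: List[_Shift],
        classes: List[RateClass],
        loglik: float,
        aicc_value: float,
        step_log: List[dict],
    ):
        self.model = model
        self._shifts = shifts
        self.classes = classes
        self.loglik = loglik
        self.aicc = aicc_value
        self.k = model._k(len(classes))
        self.n_obs = model.n_obs
        self.step_log = pd.DataFrame(step_log)
        flat = model._flat
        self.branch_class, self.node_class = _assignment(flat, shifts)
        self.shifts = []
        for ci, sh in enumerate(shifts):
            new = classes[ci + 1]
            if sh.placement == "node":
                # surrounding class = class of the shift node's own branch
                parent_class = int(self.branch_class[sh.node])
            else:
                # stem shift: class at the split above the shifted branch
                parent_class = int(self.node_class[flat.parent[sh.node]])
            old = classes[parent_class]
            delta_r = new.r - old.r
            self.shifts.append(
                {
                    "node": sh.node,
                    "placement": sh.placement,
                    "bipartition": flat.bipartition[sh.node],
                    "class_id": ci + 1,
                    "b": new.b,
                    "d": new.d,
                    "r": new.r,
                    "eps": new.eps,
                    "delta_r": delta_r,
                    "direction": "up" if delta_r > 0 else "down",
                    "age_stem": float(flat.t_top[sh.node]),
                }
            )

    @property
    def n_shifts(self) -> int:
        return len(self._shifts)

    def class_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "class_id": rc.class_id,
                    "b": rc.b,
                    "d": rc.d,
                    "r": rc.r,
                    "eps": rc.eps,
                    "tau": rc.tau,
                    "loglik": rc.loglik,
                    "n_branches": rc.n_branches,
                }
                for rc in self.classes
            ]
        )

    def branch_rates(self) -> Dict[Node, RateClass]:
        """Rate class carried by each non-root branch, keyed by child node."""
        flat = self.model._flat
        return {
            flat.nodes[i]: self.classes[self.branch_class[i]]
            for i in range(1, len(flat.nodes))
        }

    def summary(self) -> str:
        lines = [
            "Birth-death shift model (stepwise AICc)",
            f"  tips: {self.model._flat.n_tips}   n_obs: {self.n_obs}   "
            f"k: {self.k}   logL: {self.loglik:.4f}   AICc: {self.aicc:.4f}",
            f"  accepted shifts: {self.n_shifts}",
            self.class_table().round(5).to_string(index=False),
        ]
        for sh in self.shifts:
            preview = ",".join(sorted(sh["bipartition"])[:4])
            lines.append(
                f"  shift ({sh['placement']}) at stem age {sh['age_stem']:.2f} Ma "
                f"[{preview}...] delta_r={sh['delta_r']:+.5f} ({sh['direction']})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "k": self.k,
            "n_obs": self.n_obs,
            "aicc": self.aicc,
            "classes": self.class_table().to_dict(orient="records"),
            "shifts": [
                {**{k: v for k, v in sh.items() if k != "bipartition"},
                 "bipartition": sorted(sh["bipartition"])}
                for sh in self.shifts
            ],
        }


def stepwise_search(
    tree: TimeTree,
    richness: Optional[Mapping[str, float]] = None,
    threshold: Optional[float] = None,
    placements: Sequence[str] = ("stem", "node"),
    condition_on_survival: bool = True,
    **fit_kwargs,
) -> ShiftResults:
    """Convenience wrapper: build a :class:`ShiftModel` and fit it."""
    return ShiftModel(tree, richness, condition_on_survival).fit(
        threshold=threshold, placements=placements, **fit_kwargs
    )


def summarize_shifts(
    results: Sequence[ShiftResults], min_frequency: float = 0.5
) -> pd.DataFrame:
    """Cross-tree shift summary keyed by bipartition.

    Frequency is the fraction of analyzed trees containing an accepted
    shift at the bipartition; the magnitude is the mean rate difference
    delta_r between the shifted class and its parent class.
    """
    if not results:
        raise ValueError("no fitted models to summarize")
    acc: Dict[FrozenSet[str], List[dict]] = {}
    for res in results:
        for sh in res.shifts:
            acc.setdefault(sh["bipartition"], []).append(sh)
    rows = []
    n_trees = len(results)
    for bip, hits in acc.items():
        freq = len(hits) / n_trees
        mean_dr = float(np.mean([h["delta_r"] for h in hits]))
        rows.append(
            {
                "bipartition": tuple(sorted(bip)),
                "tips_preview": ",".join(sorted(bip)[:5]),
                "n_tips": len(bip),
                "frequency": freq,
                "delta_r": mean_dr,
                "direction": "up" if mean_dr > 0 else "down",
                "mean_age_stem": float(np.mean([h["age_stem"] for h in hits])),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "bipartition", "tips_preview", "n_tips", "frequency",
            "delta_r", "direction", "mean_age_stem",
        ],
    )
    if len(df):
        df = df[df["frequency"] >= min_frequency].reset_index(drop=True)
        df = df.sort_values("frequency", ascending=False, kind="stable").reset_index(drop=True)
    return df
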