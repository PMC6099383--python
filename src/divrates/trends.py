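"""Time-sliced averages of branch-associated diversification rates.

The fitted shift model assigns every branch a rate class (b, d), hence
r = b - d, eps = d/b and tau = b + d.  Trees are cut into uniform intervals
anchored at 0 Ma (1 Myr wide by default); a branch contributes to every
interval its age span [age_child, age_parent) overlaps with positive
duration.  The slice statistic is the unweighted mean over contributing
branches (the overlap-weighted mean is available via ``weight_by_overlap``,
and is the variant invariant to subdividing a branch into collinear
segments).  Across bootstrap trees, per-slice means are averaged per slice.

Group trends restrict the average to branches whose subtended tips all
belong to one trait group (which automatically includes the group's stem
branch).
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .moments import pool_by_trait
from .shifts import RateClass, ShiftResults
from .trees import Node, TimeTree

__all__ = ["slice_tree", "trend_lines"]

_PARS = ("r", "eps", "tau")


def _branch_arrays(
    tree: TimeTree, branch_rates: Mapping[Node, RateClass]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[Node]]:
    nodes = [n for n in tree.nodes if n.parent is not None]
    missing = [n for n in nodes if n not in branch_rates]
    if missing:
        lab = missing[0].label or "an internal node"
        raise ValueError(f"branch above {lab} carries no rate class")
    top = np.array([tree.age(n.parent) for n in nodes])
    bot = np.array([tree.age(n) for n in nodes])
    rates = np.array(
        [[branch_rates[n].r, branch_rates[n].eps, branch_rates[n].tau] for n in nodes]
    )
    return top, bot, rates, nodes


def slice_tree(
    tree: TimeTree,
    branch_rates: Mapping[Node, RateClass],
    width: float = 1.0,
    weight_by_overlap: bool = False,
    branch_filter: Optional[Sequence[Node]] = None,
) -> pd.DataFrame:
    """Per-interval mean r, eps and tau over branches crossing each interval.

    Intervals are [k*width + width, k*width) in Ma; intervals older than the
    root age are absent.  ``branch_filter`` restricts the average to the
    given child nodes' branches (used for trait-group trends).
    """
    if width <= 0:
        raise ValueError("slice width must be positive")
    top, bot, rates, nodes = _branch_arrays(tree, branch_rates)
    if branch_filter is not None:
        wanted = {id(n) for n in branch_filter}
        mask = np.array([id(n) in wanted for n in nodes])
        top, bot, rates = top[mask], bot[mask], rates[mask]
        if not len(top):
            return pd.DataFrame(
                columns=["interval_old", "interval_young", "mean_r", "mean_eps",
                         "mean_tau", "n_branches"]
            )
    n_slices = int(np.ceil(max(top.max(), 1e-12) / width - 1e-9))
    rows = []
    for k in range(n_slices - 1, -1, -1):
        e_old, e_young = (k + 1) * width, k * width
        overlap = np.minimum(top, e_old) - np.maximum(bot, e_young)
        hit = overlap > 1e-12
        if not np.any(hit):
            continue
        w = overlap[hit] if weight_by_overlap else np.ones(int(hit.sum()))
        mean = (rates[hit] * w[:, None]).sum(axis=0) / w.sum()
        rows.append(
            {
                "interval_old": e_old,
                "interval_young": e_young,
                "mean_r": mean[0],
                "mean_eps": mean[1],
                "mean_tau": mean[2],
                "n_branches": int(hit.sum()),
            }
        )
    return pd.DataFrame(rows)


def trend_lines(
    fitted: Sequence[ShiftResults],
    traits: Optional[Mapping[str, str]] = None,
    width: float = 1.0,
    weight_by_overlap: bool = False,
) -> pd.DataFrame:
    """Average per-slice rates across fitted trees, overall and per trait group.

    Groups are the most inclusive monophyletic same-category tip sets of each
    tree (categories may be paraphyletic overall); group trends average only
    branches entirely inside a group.  Trees must share a common tip set.
    Returns a tidy frame with one row per (interval, group).
    """
    if not fitted:
        raise ValueError("no fitted models given")
    tip_sets = {frozenset(res.model.tree.tip_labels) for res in fitted}
    if len(tip_sets) != 1:
        raise ValueError("trees must share an identical tip set")
    per_group_frames: Dict[str, List[pd.DataFrame]] = {}
    for res in fitted:
        tree = res.model.tree
        rates = res.branch_rates()
        per_group_frames.setdefault("all", []).append(
            slice_tree(tree, rates, width, weight_by_overlap)
        )
        if traits is not None:
            bips = tree.bipartitions()
            for group in pool_by_trait(tree, traits):
                members = [
                    n for n in tree.nodes
                    if n.parent is not None and bips[n] <= group.tips
                ]
                frame = slice_tree(
                    tree, rates, width, weight_by_overlap, branch_filter=members
                )
                per_group_frames.setdefault(group.category, []).append(frame)
    out = []
    for group, frames in per_group_frames.items():
        pooled = pd.concat(frames, ignore_index=True)
        if pooled.empty:
            continue
        agg = (
            pooled.groupby(["interval_old", "interval_young"], as_index=False)
            .agg(
                mean_r=("mean_r", "mean"),
                mean_eps=("mean_eps", "mean"),
                mean_tau=("mean_tau", "mean"),
                n_branches=("n_branches", "sum"),
                n_trees=("mean_r", "size"),
            )
            .sort_values("interval_old", ascending=False)
        )
        agg.insert(2, "group", group)
        out.append(agg)
    return pd.concat(out, ignore_index=True)
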