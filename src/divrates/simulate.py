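"""Synthetic data generators with known ground truth.

Everything the pipeline consumes can be generated here: ultrametric
birth-death trees (optionally with a planted rate shift), genus-style
collapsed richness tables, fossil first/last occurrence ranges from a
constant-rates budding-speciation process (complete or Poisson-thinned
preservation), and nested trait maps.

All generators are deterministic given their seed (numpy ``default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fossil import FossilRangeTable
from .trees import Node, TimeTree

__all__ = [
    "PlantedShift",
    "simulate_bd_tree",
    "collapse_to_richness",
    "simulate_fossil_ranges",
    "assign_traits",
]

RETRY_CAP = 1000


@dataclass
class PlantedShift:
    """A rate shift planted during forward simulation.

    The shift triggers either when the extant lineage count first reaches
    ``at_count`` or at forward time ``at_time``; the next lineage born after
    the trigger founds the shifted subtree, which evolves under (b, d) from
    the very start of its stem branch (so the planted rates hold for the
    entire stem + subtree, matching stem-placement shift semantics).
    ``min_clade`` / ``max_clade`` (extant tips of the shifted clade at the
    end) let the caller insist on a detectably large planted clade;
    simulations failing the constraint are redrawn.
    """

    b: float
    d: float = 0.0
    at_count: Optional[int] = None
    at_time: Optional[float] = None
    min_clade: int = 2
    max_clade: Optional[int] = None

    def __post_init__(self):
        if (self.at_count is None) == (self.at_time is None):
            raise ValueError("specify exactly one of at_count / at_time")
        if self.b <= 0 or self.d < 0:
            raise ValueError("invalid planted rates")


class _Lineage:
    __slots__ = ("node", "start", "cls")

    def __init__(self, node: Node, start: float, cls: int):
        self.node = node
        self.start = start
        self.cls = cls


def _simulate_once(
    b: float,
    d: float,
    age: Optional[float],
    ntips: Optional[int],
    shift: Optional[PlantedShift],
    rng: np.random.Generator,
) -> Optional[Tuple[TimeTree, dict]]:
    rates = [(b, d)]
    if shift is not None:
        rates.append((shift.b, shift.d))
    root = Node()
    active: List[_Lineage] = [_Lineage(root, 0.0, 0)]
    t = 0.0
    shift_done = shift is None
    shift_node: Optional[Node] = None
    counter = 0
    shift_armed = False  # trigger reached; next newborn founds the shifted subtree
    while True:
        n_ext = len(active)
        if n_ext == 0:
            return None  # whole clade extinct
        if not shift_done and shift.at_count is not None and n_ext >= shift.at_count:
            shift_armed = True
        total = sum(rates[l.cls][0] + rates[l.cls][1] for l in active)
        if total <= 0:
            dt = math.inf
        else:
            dt = rng.exponential(1.0 / total)
        if (
            not shift_done
            and shift.at_time is not None
            and t + dt >= shift.at_time
            and not shift_armed
        ):
            shift_armed = True
        if age is not None and t + dt >= age:
            t = age
            break
        t += dt
        # choose the lineage proportionally to its total event rate
        weights = np.array([rates[l.cls][0] + rates[l.cls][1] for l in active])
        i = int(rng.choice(n_ext, p=weights / weights.sum()))
        lin = active[i]
        bb, dd = rates[lin.cls]
        if rng.random() < bb / (bb + dd):
            # birth: the pending branch ends in a split
            lin.node.length = t - lin.start if lin.node.parent is not None else 0.0
            c1, c2 = Node(), Node()
            lin.node.add_child(c1)
            lin.node.add_child(c2)
            active[i] = _Lineage(c1, t, lin.cls)
            active.append(_Lineage(c2, t, lin.cls))
            if shift_armed and not shift_done:
                active[-1].cls = 1
                shift_node = c2
                shift_done = True
            if ntips is not None and len(active) >= ntips:
                # declare the present strictly between this and the next event
                total = sum(rates[l.cls][0] + rates[l.cls][1] for l in active)
                t += rng.exponential(1.0 / total)
                break
        else:
            # death: close the branch as an extinct tip
            lin.node.length = t - lin.start if lin.node.parent is not None else 0.0
            counter += 1
            lin.node.label = f"x{counter}"
            active.pop(i)
    # close surviving branches at the present
    ext_labels = []
    for j, lin in enumerate(active):
        if lin.node.parent is not None:
            lin.node.length = t - lin.start
        lin.node.label = f"t{j + 1}"
        ext_labels.append(lin.node.label)
    if len(ext_labels) < 2:
        return None
    full = TimeTree(root, validate=False)
    shifted_tips = frozenset()
    if shift_node is not None:
        shifted_tips = frozenset(
            lab for lab in full.bipartition(shift_node) if lab.startswith("t")
        )
    recon = full.retain_tips(ext_labels)
    if shift is not None:
        if len(shifted_tips) < shift.min_clade:
            return None
        if shift.max_clade is not None and len(shifted_tips) > shift.max_clade:
            return None
        if len(shifted_tips) >= recon.n_tips:  # shift swallowed the whole tree
            return None
    info = {
        "duration": t,
        "n_tips": recon.n_tips,
        "base_rates": (b, d),
        "shift_rates": (shift.b, shift.d) if shift is not None else None,
        "shift_tips": shifted_tips,
    }
    return recon, info


def simulate_bd_tree(
    b: float,
    d: float = 0.0,
    *,
    age: Optional[float] = None,
    ntips: Optional[int] = None,
    shift: Optional[PlantedShift] = None,
    seed: int,
    retry_cap: int = RETRY_CAP,
) -> Tuple[TimeTree, dict]:
    """Forward (Gillespie) birth-death simulation of a reconstructed tree.

    Exactly one stop condition must be given: ``age`` (Myr of forward time)
    or ``ntips`` (extant lineage count at which the present is declared).
    Extinct lineages are pruned; the returned tree is the reconstructed
    (extant-only) tree, conditioned on >= 2 surviving tips by redrawing up
    to ``retry_cap`` times.
    """
    if b <= 0 or d < 0:
        raise ValueError(f"invalid rates b={b}, d={d}")
    if (age is None) == (ntips is None):
        raise ValueError("specify exactly one of age / ntips")
    if ntips is not None and ntips < 2:
        raise ValueError("ntips must be >= 2")
    rng = np.random.default_rng(seed)
    for attempt in range(retry_cap):
        out = _simulate_once(b, d, age, ntips, shift, rng)
        if out is not None:
            tree, info = out
            info["seed"] = seed
            info["attempts"] = attempt + 1
            return tree, info
    raise RuntimeError(
        f"no surviving clade in {retry_cap} attempts (b={b}, d={d}); "
        "increase retry_cap or the net diversification"
    )


def collapse_to_richness(
    tree: TimeTree, groups: Mapping[str, str]
) -> Tuple[TimeTree, pd.DataFrame]:
    """Collapse monophyletic tip groups into single exemplar tips with richness.

    Each group must be a clade of the tree.  The retained tip is the
    lexicographically smallest member; after unifurcation suppression its
    pendant branch spans the group's stem age exactly.  Returns the pruned
    tree and a ``tip,n_species`` table keyed by the retained tip labels.
    """
    by_group: Dict[str, List[str]] = {}
    for tip in tree.tip_labels:
        if tip not in groups:
            raise KeyError(f"tip {tip!r} missing from the group map")
        by_group.setdefault(groups[tip], []).append(tip)
    bips = {bip for bip in tree.bipartitions().values()}
    for gid, members in by_group.items():
        if len(members) > 1 and frozenset(members) not in bips:
            raise ValueError(f"group {gid!r} is not monophyletic on this tree")
    pruned = tree.prune_to_exemplars(groups)
    rows = [
        {"tip": min(members), "group": gid, "n_species": len(members)}
        for gid, members in sorted(by_group.items())
    ]
    richness = pd.DataFrame(rows).sort_values("tip").reset_index(drop=True)
    return pruned, richness


def simulate_fossil_ranges(
    b: float,
    d: float,
    *,
    duration: float,
    n_founders: int = 1,
    preservation_rate: Optional[float] = None,
    seed: int,
) -> FossilRangeTable:
    """Species-level budding birth-death process observed as fossil ranges.

    Each birth founds a new taxon while the mother persists (budding
    speciation, the concept matching boundary-crosser estimators).  With
    complete preservation (``preservation_rate=None``) the range of a taxon
    is its true lifespan: FAD = origination age, LAD = extinction age (0 for
    extant taxa).  With a finite Poisson preservation rate per Myr, FAD/LAD
    are the oldest/youngest sampled occurrences and unsampled taxa are
    dropped.
    """
    if b <= 0 or d < 0 or duration <= 0 or n_founders < 1:
        raise ValueError("invalid simulation parameters")
    if preservation_rate is not None and preservation_rate <= 0:
        raise ValueError("preservation rate must be positive (or None for complete)")
    rng = np.random.default_rng(seed)
    origin: List[float] = [0.0] * n_founders
    death: List[Optional[float]] = [None] * n_founders
    alive: List[int] = list(range(n_founders))
    t = 0.0
    while alive:
        n = len(alive)
        t += rng.exponential(1.0 / ((b + d) * n))
        if t >= duration:
            break
        i = int(rng.integers(n))
        if rng.random() < b / (b + d):
            origin.append(t)
            death.append(None)
            alive.append(len(origin) - 1)
        else:
            death[alive[i]] = t
            alive[i] = alive[-1]
            alive.pop()
    taxa, fads, lads = [], [], []
    for idx in range(len(origin)):
        t0 = origin[idx]
        t1 = death[idx] if death[idx] is not None else duration
        if preservation_rate is None:
            fad, lad = duration - t0, duration - t1
        else:
            k = rng.poisson(preservation_rate * (t1 - t0))
            if k == 0:
                continue
            occ = rng.uniform(t0, t1, size=k)
            fad, lad = duration - occ.min(), duration - occ.max()
        taxa.append(f"s{idx + 1}")
        fads.append(fad)
        lads.append(lad)
    return FossilRangeTable(
        taxon=np.array(taxa), fad=np.array(fads), lad=np.array(lads)
    )


def assign_traits(
    tree: TimeTree,
    transitions: Sequence[Tuple[Iterable[str], str]] = (),
    background: str = "ON",
) -> pd.DataFrame:
    """Nested trait categories on tips: background plus clade transitions.

    Each transition is ``(tip selector, category)``; the selector's MRCA
    clade takes the category.  Transition clades must be nested or disjoint
    (emulating the oogamous -> anisogamous -> motile nesting); overlapping
    non-nested clades raise an error.  Inner transitions override outer
    ones.
    """
    clades = []
    for selector, category in transitions:
        node = tree.mrca(list(selector))
        clades.append((tree.bipartition(node), category))
    for i in range(len(clades)):
        for j in range(i + 1, len(clades)):
            a, c = clades[i][0], clades[j][0]
            if a & c and not (a <= c or c <= a):
                raise ValueError(
                    "transition clades overlap without nesting: "
                    f"{sorted(a)[:3]}... vs {sorted(c)[:3]}..."
                )
    assignment = {tip: background for tip in tree.tip_labels}
    for clade, category in sorted(clades, key=lambda x: -len(x[0])):
        for tip in clade:
            assignment[tip] = category
    return pd.DataFrame(
        {"tip": list(assignment), "category": list(assignment.values())}
    ).sort_values("tip").reset_index(drop=True)
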