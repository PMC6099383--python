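"""Time-calibrated tree data model.

A :class:`TimeTree` is a rooted tree with branch lengths in Myr.  Node ages
(Ma) are always derived from branch lengths: the root age is the maximum
root-to-tip path length, and every other node sits at ``root_age - depth``.
For an ultrametric tree of extant taxa all tips therefore sit at age 0.

Newick parsing is delegated to :mod:`dendropy`; writing is done directly so
that a write/read round trip preserves branch lengths to within float
representation.  Polytomies are first-class citizens throughout.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional

import dendropy

__all__ = [
    "Node",
    "TimeTree",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "read_newick_file",
    "read_exemplar_csv",
]

ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised for malformed Newick input; message includes the position."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates TimeTree invariants."""


class Node:
    """A tree node with a parent link, children, and a subtending branch length."""

    __slots__ = ("parent", "children", "length", "label")

    def __init__(self, length: float = 0.0, label: Optional[str] = None):
        self.parent: Optional[Node] = None
        self.children: List[Node] = []
        self.length = float(length)
        self.label = label

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label or ''} {kind} len={self.length:g}>"


class TimeTree:
    """Rooted, branch-length-bearing tree with derived node ages in Ma."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self.root.parent = None
        self.root.length = 0.0
        self._ages: Optional[Dict[Node, float]] = None
        if validate:
            self.validate()

    # ------------------------------------------------------------------ basics
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    @property
    def nodes(self) -> List[Node]:
        return list(self.preorder())

    @property
    def tips(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> List[str]:
        return [t.label for t in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def validate(self) -> None:
        labels = [t.label for t in self.tips]
        if any(lab is None or lab == "" for lab in labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise TreeValidationError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        for node in self.preorder():
            if node is not self.root and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} above {node.label or 'internal node'}"
                )

    # -------------------------------------------------------------------- ages
    def _compute_ages(self) -> Dict[Node, float]:
        depth: Dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            depth[node] = depth[node.parent] + node.length
        root_age = max(depth[t] for t in self.tips)
        return {n: root_age - d for n, d in depth.items()}

    @property
    def ages(self) -> Dict[Node, float]:
        if self._ages is None:
            self._ages = self._compute_ages()
        return self._ages

    def age(self, node: Node) -> float:
        return self.ages[node]

    @property
    def root_age(self) -> float:
        return self.ages[self.root]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        root_age = self.root_age
        tol = rtol * max(root_age, 1.0)
        return all(abs(self.ages[t]) <= tol for t in self.tips)

    def _invalidate(self) -> None:
        self._ages = None

    # ------------------------------------------------------------------- query
    def tip_map(self) -> Dict[str, Node]:
        return {t.label: t for t in self.tips}

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the given tip labels."""
        tip_map = self.tip_map()
        want = list(labels)
        missing = [lab for lab in want if lab not in tip_map]
        if missing:
            raise KeyError(f"unknown tip label(s): {', '.join(sorted(missing))}")
        if len(want) == 1:
            return tip_map[want[0]]
        # Intersect root-paths; the deepest shared node is the MRCA.
        paths = []
        for lab in want:
            node = tip_map[lab]
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def bipartition(self, node: Node) -> FrozenSet[str]:
        """Canonical key for the branch above ``node``: the subtended tip set."""
        if node.is_tip:
            return frozenset([node.label])
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_tip:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def bipartitions(self) -> Dict[Node, FrozenSet[str]]:
        keys: Dict[Node, FrozenSet[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                keys[node] = frozenset([node.label])
            else:
                acc = frozenset()
                for c in node.children:
                    acc = acc | keys[c]
                keys[node] = acc
        return keys

    # ----------------------------------------------------------------- editing
    def copy(self) -> "TimeTree":
        mapping: Dict[Node, Node] = {}
        new_root = Node(self.root.length, self.root.label)
        mapping[self.root] = new_root
        for node in self.preorder():
            if node is self.root:
                continue
            clone = Node(node.length, node.label)
            mapping[node.parent].add_child(clone)
            mapping[node] = clone
        return TimeTree(new_root, validate=False)

    def prune_to_exemplars(self, exemplar_map: Mapping[str, str]) -> "TimeTree":
        """Keep one tip per exemplar group; suppress resulting degree-2 nodes.

        The retained representative is the lexicographically smallest tip
        label within each group, a deterministic choice.  Node ages of every
        retained node are unchanged.
        """
        tips = self.tip_labels
        missing = [t for t in tips if t not in exemplar_map]
        if missing:
            raise KeyError(f"exemplar map does not cover tip(s): {', '.join(sorted(missing))}")
        keep: Dict[str, str] = {}
        for tip in tips:
            group = exemplar_map[tip]
            if group not in keep or tip < keep[group]:
                keep[group] = tip
        return self.retain_tips(set(keep.values()))

    def retain_tips(self, labels: Iterable[str]) -> "TimeTree":
        """Subtree induced by the given tips, with unifurcations suppressed."""
        wanted = set(labels)
        if not wanted:
            raise ValueError("cannot retain an empty tip set")
        unknown = wanted - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tip label(s): {', '.join(sorted(unknown))}")
        tree = self.copy()
        # Drop unwanted tips, then iteratively clean up.
        changed = True
        while changed:
            changed = False
            for node in list(tree.preorder()):
                if node.is_tip and node.label not in wanted and node.parent is not None:
                    node.parent.children.remove(node)
                    changed = True
                elif (not node.children) and node.label is None and node.parent is not None:
                    node.parent.children.remove(node)  # emptied internal node
                    changed = True
                elif len(node.children) == 1 and node.parent is not None:
                    child = node.children[0]
                    child.length += node.length
                    child.parent = node.parent
                    idx = node.parent.children.index(node)
                    node.parent.children[idx] = child
                    changed = True
        root = tree.root
        while len(root.children) == 1:
            root = root.children[0]
            root.parent = None
            root.length = 0.0
        return TimeTree(root, validate=False)

    # --------------------------------------------------------------------- io
    def write_newick(self, float_fmt: str = "%.12g") -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = _quote_label(node.label)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += _quote_label(node.label)
            if node.parent is not None:
                core += ":" + (float_fmt % node.length)
            return core

        return fmt(self.root) + ";"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[]' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    mapping: Dict[object, Node] = {}
    droot = dtree.seed_node
    root = Node(0.0, _dlabel(droot))
    mapping[droot] = root
    for dnode in dtree.preorder_node_iter():
        if dnode is droot:
            continue
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        mapping[dnode.parent_node].add_child(Node(length, _dlabel(dnode)))
        mapping[dnode] = mapping[dnode.parent_node].children[-1]
    return TimeTree(root)


def _dlabel(dnode) -> Optional[str]:
    if dnode.taxon is not None and dnode.taxon.label:
        return dnode.taxon.label
    return dnode.label or None


def read_newick(text: str, ultrametric: bool = False) -> TimeTree:
    """Parse a single Newick tree.

    Parameters
    ----------
    text : str
        Newick string with branch lengths; polytomies and quoted labels are
        permitted.
    ultrametric : bool
        If True, require all tip ages to be 0 within a relative tolerance of
        1e-6 of the root age.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises DataError subclasses with position info
        if "Duplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip label: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if ultrametric and not tree.is_ultrametric():
        worst = max(abs(tree.age(t)) for t in tree.tips)
        raise TreeValidationError(
            f"tree is not ultrametric: a tip sits {worst:g} Myr away from the present"
        )
    return tree


def read_newick_file(path: str, ultrametric: bool = False) -> List[TimeTree]:
    """Read one tree per non-empty line (bootstrap-set convention)."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                trees.append(read_newick(line, ultrametric=ultrametric))
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return trees


def read_exemplar_csv(path_or_buffer) -> Dict[str, str]:
    """Read a two-column ``tip,group`` CSV into an exemplar map."""
    import pandas as pd

    df = pd.read_csv(path_or_buffer, comment="#")
    if df.shape[1] < 2:
        raise ValueError("exemplar map CSV needs two columns: tip,group")
    tip_col, group_col = df.columns[:2]
    return dict(zip(df[tip_col].astype(str), df[group_col].astype(str)))
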