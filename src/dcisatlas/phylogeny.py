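"""Maximum-parsimony trees over region copy-number characters.

Each microdissected region contributes one row of a character matrix
(columns = shared copy-number segments; values -1 loss, 0 neutral,
optionally +1 gain, NaN undetermined).  Trees are rooted at an inferred
normal diploid ancestor whose state is all-neutral; the ancestor hangs
above the most recent common ancestor of the regions via a trunk branch,
so alterations shared by every region are placed on the trunk.

Small-parsimony scoring is exact unit-cost dynamic programming per column
(the Sankoff recursion, which — unlike plain Fitch set arithmetic — stays
exact when leaves are ambiguous) with the root constrained to the neutral
state; undetermined values act as wildcards (every state at no cost).  Tree search enumerates *all*
rooted binary topologies — (2n-3)!! of them — which is exact and fast up
to the 8 regions a microdissection study realistically yields; ties are
broken deterministically by the lexicographically smallest canonical
newick string, and the number of co-optimal topologies is reported so
ambiguity stays visible.

After a tree is built, :func:`assign_branch_events` fixes ancestral states
(root-to-tip, preferring neutral on ties), sets integer Hamming branch
lengths, and places each segment character — and, optionally, each
mutation from a multi-region presence matrix — on the branch where its
state changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "PhyloTree",
    "parsimony_score",
    "build_mp_tree",
    "assign_branch_events",
    "clade_sets",
]

MAX_EXHAUSTIVE_LEAVES = 8



@dataclass
class Node:
    """Tree node; ``length``/``events`` describe the branch above it."""

    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: int | None = None
    events: list[str] = field(default_factory=list)
    states: np.ndarray | None = None  # assigned per-column states

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]


@dataclass
class PhyloTree:
    """Rooted tree: diploid ancestor -> trunk -> binary topology on regions."""

    root: Node  # the diploid ancestor; exactly one child (the regions' MRCA)
    score: int | None = None
    n_cooptimal: int | None = None
    columns: tuple[str, ...] = ()
    unplaced: list[str] = field(default_factory=list)

    @property
    def mrca(self) -> Node:
        return self.root.children[0]

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self, include_events: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name.replace(" ", "_")
            if node.length is not None:
                s += f":{node.length}"
            if include_events and node.events:
                s += "[&events={" + "|".join(node.events) + "}]"
            return s

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# topology enumeration (nested tuples over leaf indices)


def _insertions(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def _topologies(n: int):
    """All rooted binary labeled topologies on leaves 0..n-1 ((2n-3)!! of them)."""

    def rec(k, tree):
        if k == n:
            yield tree
            return
        for t in _insertions(tree, k):
            yield from rec(k + 1, t)

    if n == 1:
        yield 0
    else:
        yield from rec(2, (0, 1))


def _canonical(tree, names: Sequence[str]) -> str:
    if not isinstance(tree, tuple):
        return names[tree]
    a = _canonical(tree[0], names)
    b = _canonical(tree[1], names)
    return f"({a},{b})" if a <= b else f"({b},{a})"


# state order used in cost arrays
_STATES = (-1, 0, 1)
_INF = np.float64(1e9)


def _leaf_costs(matrix: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-leaf (3, n_columns) unit-cost arrays; NaN is a free wildcard."""
    costs = {}
    for rid, row in matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        c = np.zeros((3, vals.size))
        for i, s in enumerate(_STATES):
            observed = ~np.isnan(vals)
            c[i, observed & (vals != s)] = _INF
        costs[str(rid)] = c
    return costs


def _combine_child(cost: np.ndarray) -> np.ndarray:
    """min over child state t of cost[t] + (s != t), for each parent state s."""
    return np.minimum(cost, cost.min(axis=0, keepdims=True) + 1.0)


def _sankoff_arrays(tree, costs_by_index: Sequence[np.ndarray]) -> np.ndarray:
    """(3, n_columns) minimal subtree cost per root state, nested-tuple tree."""
    if not isinstance(tree, tuple):
        return costs_by_index[tree]
    left = _sankoff_arrays(tree[0], costs_by_index)
    right = _sankoff_arrays(tree[1], costs_by_index)
    return _combine_child(left) + _combine_child(right)


def _score_topology(tree, costs_by_index: Sequence[np.ndarray]) -> int:
    cost = _sankoff_arrays(tree, costs_by_index)
    # diploid-ancestor constraint: one more change unless the subtree root
    # can take the neutral state at no extra cost
    return int(_combine_child(cost)[1].sum())


def _tuple_to_nodes(tree, names: Sequence[str]) -> Node:
    if not isinstance(tree, tuple):
        return Node(name=names[tree])
    # order children canonically for a deterministic tree object
    kids = sorted(
        (_tuple_to_nodes(t, names) for t in tree),
        key=lambda n: _node_canonical(n),
    )
    return Node(children=kids)


def _node_canonical(node: Node) -> str:
    if node.is_leaf:
        return node.name or ""
    return "(" + ",".join(sorted(_node_canonical(c) for c in node.children)) + ")"


def parsimony_score(tree: PhyloTree, matrix: pd.DataFrame) -> int:
    """Minimal number of state changes on the tree, diploid root constrained.

    Exact small parsimony (unit-cost Sankoff recursion) summed over
    columns.  Undetermined (NaN) characters are wildcards: they accept
    any state at no cost; a fully missing column scores 0 on every
    topology.
    """
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in matrix.index]
    if missing:
        raise KeyError(f"leaves without a matrix row: {missing}")
    costs = _leaf_costs(matrix)

    def rec(node: Node) -> np.ndarray:
        if node.is_leaf:
            return costs[node.name]
        return sum(_combine_child(rec(c)) for c in node.children)

    return int(_combine_child(rec(tree.mrca))[1].sum())


def build_mp_tree(matrix: pd.DataFrame) -> tuple[PhyloTree, int]:
    """Exhaustive maximum-parsimony search over rooted topologies.

    Returns the minimum-score tree (ties broken by the lexicographically
    smallest canonical newick) together with the number of co-optimal
    topologies.  Limited to 2-8 regions, where exhaustive enumeration is
    exact and affordable.
    """
    names = [str(i) for i in matrix.index]
    n = len(names)
    if n < 2:
        raise ValueError("build_mp_tree requires at least 2 regions")
    if n > MAX_EXHAUSTIVE_LEAVES:
        raise ValueError(
            f"{n} regions exceed the exhaustive-enumeration bound of "
            f"{MAX_EXHAUSTIVE_LEAVES}; reduce the region set"
        )
    costs = _leaf_costs(matrix)
    costs_by_index = [costs[name] for name in names]

    best_score = math.inf
    best_tree = None
    best_canon = None
    n_cooptimal = 0
    for topo in _topologies(n):
        score = _score_topology(topo, costs_by_index)
        if score < best_score:
            best_score = score
            best_tree = topo
            best_canon = _canonical(topo, names)
            n_cooptimal = 1
        elif score == best_score:
            n_cooptimal += 1
            canon = _canonical(topo, names)
            if canon < best_canon:
                best_tree = topo
                best_canon = canon

    mrca = _tuple_to_nodes(best_tree, names)
    root = Node(name="diploid ancestor", children=[mrca], length=0)
    tree = PhyloTree(
        root=root,
        score=int(best_score),
        n_cooptimal=n_cooptimal,
        columns=tuple(map(str, matrix.columns)),
    )
    return tree, n_cooptimal


# ---------------------------------------------------------------------------
# ancestral states, branch lengths, event placement


def _event_label(column: str, new_state: int) -> str:
    kind = {-1: "loss", 1: "gain", 0: "neutral"}[new_state]
    return f"{column}:{kind}"


def _normalize_presence(presence: pd.DataFrame) -> pd.DataFrame:
    def conv(v):
        if isinstance(v, str):
            return {"present": 1.0, "absent": 0.0, "unknown": float("nan")}[v]
        return float(v)

    return presence.map(conv)


def assign_branch_events(
    tree: PhyloTree,
    matrix: pd.DataFrame,
    presence: pd.DataFrame | None = None,
) -> PhyloTree:
    """Fix ancestral states, branch lengths, and event placement in place.

    Ancestral states come from a root-to-tip pass over the Fitch state
    sets: a child keeps its parent's state when allowed, otherwise prefers
    neutral, otherwise the smallest available state.  Branch length is the
    Hamming distance between endpoint state vectors, skipping columns
    where a leaf's observation is missing.  Each character is recorded as
    an event on every branch where its state changes; mutations from the
    optional presence matrix (rows = leaves, values present/absent/unknown
    or 1/0/NaN) are placed on the branch above the most recent common
    ancestor of the present leaves, the trunk when present everywhere, and
    flagged unplaced when no single branch is compatible (homoplasy).
    """
    leaves = tree.leaf_names()
    if any(l not in matrix.index for l in leaves):
        raise KeyError("tree leaf without a matrix row")
    columns = list(map(str, matrix.columns))
    leaf_costs = _leaf_costs(matrix)
    n_col = len(columns)

    # bottom-up exact subtree costs per state (unit-cost Sankoff)
    costs: dict[int, np.ndarray] = {}
    for node in tree.mrca.postorder():
        if node.is_leaf:
            costs[id(node)] = leaf_costs[node.name]
        else:
            costs[id(node)] = sum(_combine_child(costs[id(c)]) for c in node.children)

    # top-down state assignment; the ancestor is all-neutral by model.
    # At each node pick a state realizing the parental minimum, keeping
    # the parent's state when optimal, then preferring neutral on ties.
    tree.root.states = np.zeros(n_col, dtype=np.int8)
    tree.root.length = 0
    state_index = {s: i for i, s in enumerate(_STATES)}

    def assign(node: Node, parent_states: np.ndarray) -> None:
        c = costs[id(node)]
        states = np.empty(n_col, dtype=np.int8)
        for j in range(n_col):
            p = int(parent_states[j])
            col = c[:, j]
            target = min(col[state_index[s]] + (s != p) for s in _STATES)
            for s in (p, 0, -1, 1):  # tie preference: parent, then neutral
                if col[state_index[s]] + (s != p) == target:
                    states[j] = s
                    break
        node.states = states
        if node.is_leaf:
            observed = matrix.loc[node.name].to_numpy(dtype=float)
            informative = ~np.isnan(observed)
        else:
            informative = np.ones(n_col, dtype=bool)
        changed = (states != parent_states) & informative
        node.length = int(changed.sum())
        node.events = [
            _event_label(columns[j], int(states[j])) for j in np.flatnonzero(changed)
        ]
        for c in node.children:
            assign(c, states)

    assign(tree.mrca, tree.root.states)

    tree.unplaced = []
    if presence is not None:
        pres = _normalize_presence(presence)
        missing_rows = [l for l in leaves if l not in pres.index]
        if missing_rows:
            raise KeyError(f"presence matrix missing leaves: {missing_rows}")
        # descendant leaf sets per branch (branch = node below it)
        below: dict[int, frozenset[str]] = {}
        nodes = list(tree.mrca.postorder())
        for node in nodes:
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        for mut in pres.columns:
            col = pres[mut]
            present = {l for l in leaves if col.get(l) == 1.0}
            absent = {l for l in leaves if col.get(l) == 0.0}
            if not present:
                tree.unplaced.append(str(mut))
                continue
            # branch above the MRCA of the present leaves
            candidates = [nd for nd in nodes if present <= below[id(nd)]]
            target = min(candidates, key=lambda nd: len(below[id(nd)]))
            if below[id(target)] & absent:
                tree.unplaced.append(str(mut))
            else:
                target.events.append(f"mut:{mut}")
    return tree


def clade_sets(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial clades (leaf-name sets of internal nodes below the MRCA)."""
    out: set[frozenset[str]] = set()
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.mrca.postorder():
        if not node.is_leaf:
            clade = frozenset(node.leaf_names())
            if 1 < len(clade) < len(all_leaves):
                out.add(clade)
    return out
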