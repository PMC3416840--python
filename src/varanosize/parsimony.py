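"""Unordered-parsimony reconstruction of ancestral biogeographic areas.

States are unordered areas (any hashable label). Tips may be polymorphic
(a set of areas, e.g. a species spanning Africa and western Asia), which is
treated as free choice among the listed states. Trees are rooted and may
contain polytomies.

The reconstruction is the Fitch criterion — minimize the number of state
changes over the tree — computed exactly by 0/1-cost dynamic programming
(the Sankoff recursion with the Fitch metric), which generalizes cleanly to
polytomies and polymorphic tips. On strictly binary trees with singleton
tips the per-node sets of minimal-cost states coincide with the classical
Fitch down-pass sets. An exhaustive-enumeration oracle is provided for
small instances and backs the property tests.
"""

from __future__ import annotations

import io as _io
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy

__all__ = [
    "TreeNode",
    "AreaTree",
    "ReconstructionResult",
    "NewickParseError",
    "parse_newick",
    "read_tip_states",
    "fitch_reconstruct",
    "brute_force_min_length",
]


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate leaves...)."""


@dataclass
class TreeNode:
    """A node of a rooted tree; leaves carry taxon labels."""

    label: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class AreaTree:
    """Rooted tree with unique leaf labels; branch lengths are ignored."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self.nodes: list[TreeNode] = []
        stack = [root]
        seen_ids = set()
        while stack:
            node = stack.pop()
            if id(node) in seen_ids:
                raise ValueError("tree contains a cycle or shared subtree")
            seen_ids.add(id(node))
            self.nodes.append(node)
            stack.extend(reversed(node.children))
        self.leaves = [n for n in self.nodes if n.is_leaf]
        labels = [n.label for n in self.leaves]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise ValueError("every leaf must carry a label")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate leaf labels: {sorted(dupes)}")
        self.internal = [n for n in self.nodes if not n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def __len__(self) -> int:
        return len(self.nodes)


def parse_newick(text: str) -> AreaTree:
    """Parse a newick string (semicolon-terminated) into an :class:`AreaTree`.

    Polytomies are preserved; branch lengths and internal labels are kept
    but play no role in the reconstruction.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError("newick string must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:
        raise NewickParseError(f"could not parse newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        return TreeNode(label=label, children=[convert(c) for c in dnode.child_nodes()])

    return AreaTree(convert(dtree.seed_node))


TipStates = Mapping[str, frozenset]


def read_tip_states(source: Union[str, _io.IOBase]) -> dict[str, frozenset[str]]:
    """Read a two-column (tab- or whitespace-delimited) leaf -> areas file.

    The second column is a comma-separated set of areas; blank lines and
    ``#`` comments are skipped.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    out: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'leaf<TAB>area[,area...]'")
        leaf, areas = parts[0].strip(), parts[1].strip()
        states = frozenset(a.strip() for a in areas.split(",") if a.strip())
        if not states:
            raise ValueError(f"line {lineno}: leaf {leaf!r} has no states")
        if leaf in out:
            raise ValueError(f"line {lineno}: duplicate leaf {leaf!r}")
        out[leaf] = states
    return out


@dataclass
class ReconstructionResult:
    """Minimum-change reconstruction of areas on a rooted tree.

    ``tree_length`` is the minimum number of state changes.
    ``downpass_sets`` holds, per node, the states of minimal subtree cost
    (classical Fitch sets on binary trees); ``final_sets`` the states each
    node takes in at least one most-parsimonious reconstruction whose root
    is optimal. Sets are keyed by node object id; use :meth:`states_of`.
    """

    tree: AreaTree
    tree_length: int
    downpass_sets: dict[int, frozenset]
    final_sets: dict[int, frozenset]

    @property
    def root_states(self) -> frozenset:
        return self.final_sets[id(self.tree.root)]

    def states_of(self, node: TreeNode) -> frozenset:
        return self.final_sets[id(node)]

    def states_by_label(self) -> dict[str, frozenset]:
        """Final state sets for every labelled node."""
        return {
            n.label: self.final_sets[id(n)]
            for n in self.tree.nodes
            if n.label is not None
        }


def _check_tips(tree: AreaTree, tips: TipStates) -> dict[str, frozenset]:
    cleaned = {}
    for leaf in tree.leaves:
        if leaf.label not in tips:
            raise KeyError(f"no area states supplied for leaf {leaf.label!r}")
        states = frozenset(tips[leaf.label])
        if not states:
            raise ValueError(f"leaf {leaf.label!r} has an empty state set")
        cleaned[leaf.label] = states
    return cleaned


def fitch_reconstruct(tree: AreaTree, tips: TipStates) -> ReconstructionResult:
    """Exact minimum-change (Fitch-criterion) reconstruction.

    Works on arbitrary rooted trees: polytomies and polymorphic tips are
    handled by the dynamic program directly rather than by ad-hoc set rules.
    """
    tip_states = _check_tips(tree, tips)
    alphabet = sorted(set().union(*tip_states.values()))

    INF = math.inf
    cost: dict[int, dict] = {}

    def down(node: TreeNode) -> None:
        if node.is_leaf:
            states = tip_states[node.label]
            cost[id(node)] = {s: (0 if s in states else INF) for s in alphabet}
            return
        for child in node.children:
            down(child)
        c: dict = {}
        for s in alphabet:
            total = 0
            for child in node.children:
                ccost = cost[id(child)]
                total += min(
                    ccost[t] + (0 if t == s else 1) for t in alphabet
                )
            c[s] = total
        cost[id(node)] = c

    down(tree.root)

    downpass_sets = {
        nid: frozenset(s for s, v in c.items() if v == min(c.values()))
        for nid, c in cost.items()
    }
    root_cost = cost[id(tree.root)]
    tree_length = int(min(root_cost.values()))

    # top-down: a state survives at a node if, for some optimal parent state,
    # it attains the child's minimal (cost + change) contribution
    final_sets: dict[int, frozenset] = {
        id(tree.root): downpass_sets[id(tree.root)]
    }

    def up(node: TreeNode) -> None:
        parent_final = final_sets[id(node)]
        for child in node.children:
            ccost = cost[id(child)]
            keep = set()
            for p in parent_final:
                best = min(ccost[t] + (0 if t == p else 1) for t in alphabet)
                keep.update(
                    t for t in alphabet if ccost[t] + (0 if t == p else 1) == best
                )
            final_sets[id(child)] = frozenset(keep)
            up(child)

    up(tree.root)

    return ReconstructionResult(
        tree=tree,
        tree_length=tree_length,
        downpass_sets=downpass_sets,
        final_sets=final_sets,
    )


def brute_force_min_length(
    tree: AreaTree,
    tips: TipStates,
    max_internal: int = 12,
    max_states: int = 5,
) -> tuple[int, frozenset]:
    """Exhaustive-enumeration oracle: minimum changes and optimal root states.

    Enumerates every assignment of single states to internal nodes; a tip
    edge costs 0 iff the parent state is in the tip's set (free choice of
    tip state). Refuses instances beyond ``max_internal`` internal nodes or
    ``max_states`` states.
    """
    tip_states = _check_tips(tree, tips)
    alphabet = sorted(set().union(*tip_states.values()))
    internal = tree.internal
    if len(internal) > max_internal:
        raise ValueError(
            f"instance too large for brute force: {len(internal)} internal nodes"
        )
    if len(alphabet) > max_states:
        raise ValueError(f"instance too large for brute force: {len(alphabet)} states")

    index = {id(n): i for i, n in enumerate(internal)}
    best = math.inf
    best_roots: set = set()
    for assign in itertools.product(alphabet, repeat=len(internal)):
        changes = 0
        for node in internal:
            s = assign[index[id(node)]]
            for child in node.children:
                if child.is_leaf:
                    if s not in tip_states[child.label]:
                        changes += 1
                else:
                    if assign[index[id(child)]] != s:
                        changes += 1
        if changes < best:
            best = changes
            best_roots = {assign[index[id(tree.root)]]} if internal else set()
        elif changes == best:
            best_roots.add(assign[index[id(tree.root)]])
    if not internal:
        # degenerate: root is itself a leaf
        return 0, frozenset(tip_states[tree.root.label])
    return int(best), frozenset(best_roots)
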