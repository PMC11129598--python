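"""A minimal clock-rooted gene-tree container.

Gene trees here are ultrametric (tip ages 0, node ages in expected
substitutions per site, strictly increasing rootward), which is exactly what
the coalescent produces and what the likelihood machinery consumes.  Newick
parsing goes through dendropy; writing is direct (branch length = parent age
minus child age).

For a clock-rooted tree, rerooting on the outgroup and pruning it is the same
operation as restricting the tree to the ingroup tips, so rooted-triple
classification reduces to comparing pairwise MRCA ages (with the structural
topology breaking exact ties from zero-length internal branches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["GeneTree", "Node", "classify_triple", "trees_to_arrays"]


@dataclass
class Node:
    age: float
    label: str | None = None
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    """Rooted ultrametric gene tree with node ages in substitutions/site."""

    root: Node
    _pair_ages: dict[frozenset, float] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    # -- basic queries -------------------------------------------------------

    def tip_labels(self) -> list[str]:
        out: list[str] = []

        def rec(n: Node) -> None:
            if n.is_leaf:
                out.append(n.label or "")
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    def pair_mrca_ages(self) -> dict[frozenset, float]:
        """MRCA age for every tip pair (cached)."""
        if self._pair_ages is not None:
            return self._pair_ages
        ages: dict[frozenset, float] = {}

        def rec(n: Node) -> list[str]:
            if n.is_leaf:
                return [n.label or ""]
            sets = [rec(c) for c in n.children]
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    for x in sets[i]:
                        for y in sets[j]:
                            ages[frozenset((x, y))] = n.age
            return [x for s in sets for x in s]

        rec(self.root)
        object.__setattr__(self, "_pair_ages", ages)
        return ages

    def mrca_age(self, x: str, y: str) -> float:
        return self.pair_mrca_ages()[frozenset((x, y))]

    def cherry_pairs(self) -> list[frozenset]:
        """Tip pairs forming two-leaf clades (used for structural tie-breaks)."""
        out: list[frozenset] = []

        def rec(n: Node) -> list[str]:
            if n.is_leaf:
                return [n.label or ""]
            sets = [rec(c) for c in n.children]
            tips = [x for s in sets for x in s]
            if len(tips) == 2:
                out.append(frozenset(tips))
            return tips

        rec(self.root)
        return out

    # -- newick --------------------------------------------------------------

    def to_newick(self, precision: int = 17) -> str:
        def rec(n: Node, parent_age: float | None) -> str:
            if n.is_leaf:
                body = n.label or ""
            else:
                body = "(" + ",".join(rec(c, n.age) for c in n.children) + ")"
            if parent_age is None:
                return body
            return f"{body}:{parent_age - n.age:.{precision}g}"

        return rec(self.root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        # node age = max distance to a descendant tip (= any, for ultrametric)
        def rec(dn) -> Node:
            if dn.is_leaf():
                return Node(age=0.0, label=dn.taxon.label if dn.taxon else dn.label)
            kids = []
            age = 0.0
            for ch in dn.child_nodes():
                sub = rec(ch)
                el = ch.edge.length if ch.edge.length is not None else 0.0
                age = max(age, sub.age + el)
                kids.append((sub, el))
            return Node(age=age, children=tuple(k for k, _ in kids))

        return cls(root=rec(dt.seed_node))

    # -- restriction / classification ----------------------------------------

    def restrict(self, labels: Sequence[str]) -> "GeneTree":
        """Induced (clock-rooted) subtree on a subset of tips."""
        labels = list(labels)
        missing = set(labels) - set(self.tip_labels())
        if missing:
            raise ValueError(f"tree is missing taxa {sorted(missing)}")

        def rec(n: Node) -> Node | None:
            if n.is_leaf:
                return n if n.label in labels else None
            kept = [k for k in (rec(c) for c in n.children) if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            return Node(age=n.age, children=tuple(kept))

        root = rec(self.root)
        assert root is not None
        return GeneTree(root=root)


def classify_triple(
    tree: GeneTree, labels: Sequence[str] = ("a", "b", "c")
) -> tuple[int, float, float]:
    """Rooted-triple topology and coalescence ages of a 3-taxon subset.

    Returns ``(topology, t1, t2)`` with topology 0 = ab|c, 1 = a|bc,
    2 = ac|b (cherry pair in the order (a,b), (b,c), (a,c)), t1 the cherry
    age and t2 the triple's root age.  Ages decide the topology; exact ties
    (zero-length internal branch) fall back to the structural topology.
    """
    a, b, c = labels
    ages = tree.pair_mrca_ages()
    pair_keys = [frozenset((a, b)), frozenset((b, c)), frozenset((a, c))]
    vals = np.array([ages[k] for k in pair_keys])
    order = np.argsort(vals, kind="stable")
    t1 = float(vals[order[0]])
    t2 = float(vals[order[2]])
    if vals[order[0]] < vals[order[1]]:
        topo = int(order[0])
    else:
        # tie: use the tree's own structure if one of the tied pairs is a cherry
        cherries = tree.restrict([a, b, c]).cherry_pairs()
        tied = [int(i) for i in order if vals[i] == vals[order[0]]]
        topo = tied[0]
        for i in tied:
            if pair_keys[i] in cherries:
                topo = int(i)
                break
    return topo, t1, t2


def trees_to_arrays(
    trees: Iterable[GeneTree],
    labels: Sequence[str] = ("a", "b", "c"),
    outgroup: str | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorize gene trees into (topology, t1, t2) arrays for the fitters.

    If ``outgroup`` is given, each tree is first checked to contain it (it is
    implicitly pruned: classification only reads the ingroup MRCA ages).
    """
    topos, t1s, t2s = [], [], []
    for i, tr in enumerate(trees):
        tips = set(tr.tip_labels())
        need = set(labels) | ({outgroup} if outgroup else set())
        if not need <= tips:
            raise ValueError(f"tree {i} is missing taxa {sorted(need - tips)}")
        topo, t1, t2 = classify_triple(tr, labels)
        topos.append(topo)
        t1s.append(t1)
        t2s.append(t2)
    return np.array(topos, dtype=int), np.array(t1s), np.array(t2s)
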