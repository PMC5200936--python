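"""Phylogenetically independent contrasts (PIC) and supporting tree tools.

A cross-species regression of protein length on exon architecture is
confounded by shared ancestry: closely related species are not independent
observations.  Felsenstein's independent contrasts fix this by transforming
n leaf values on a rooted, bifurcating tree with branch lengths into n-1
standardized differences that are mutually independent under Brownian-motion
(BM) trait evolution.  At each internal node the contrast is

    c = (x_i - x_j) / sqrt(v_i + v_j)

where v are the (extension-corrected) branch lengths of the two daughters;
the node is then assigned the 1/v-weighted mean of its daughters and its own
parent branch is extended by v_i * v_j / (v_i + v_j).  Regressions on
contrasts must be forced through the origin because the sign of each
contrast is arbitrary.

The module also provides midpoint rooting (root at the midpoint of the
longest leaf-to-leaf path — required because contrasts need a root and the
eukaryote root is contentious), pruning of zero-length terminal branches
(they break contrast standardization), a BM simulator for calibration and
power checks, and Newick I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import statsmodels.api as sm


class NewickParseError(ValueError):
    pass


class TreeStructureError(ValueError):
    """Tree unusable for the requested operation (polytomy, too few
    leaves, zero-length branches where positive ones are required)."""


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch length to the parent
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    label: str | None = None  # internal-node label for reporting

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


@dataclass
class PhyloTree:
    root: Node

    def leaves(self) -> list[Node]:
        out = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leaf_names(self) -> list[str]:
        return [l.name or "" for l in self.leaves()]

    @property
    def is_bifurcating(self) -> bool:
        def walk(n: Node) -> bool:
            if n.is_leaf:
                return True
            return len(n.children) == 2 and all(walk(c) for c in n.children)

        return walk(self.root)

    @property
    def usable_for_contrasts(self) -> bool:
        return self.n_leaves >= 2 and self.is_bifurcating

    def total_length(self) -> float:
        total = 0.0

        def walk(n: Node) -> None:
            nonlocal total
            for c in n.children:
                total += c.length
                walk(c)

        walk(self.root)
        return total

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            m = Node(name=n.name, length=n.length, label=n.label)
            for c in n.children:
                m.add(clone(c))
            return m

        return PhyloTree(root=clone(self.root))


@dataclass
class ContrastSet:
    trait: str
    contrasts: list[tuple[str, float]]  # (node id, standardized contrast)
    n_leaves: int

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.contrasts], dtype=float)


# ---------------------------------------------------------------------------
# Newick I/O

def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (with branch lengths) into a :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        n = Node(
            name=name if not dnode.child_nodes() else None,
            label=name if dnode.child_nodes() else None,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
        )
        for c in dnode.child_nodes():
            n.add(convert(c))
        return n

    tree = PhyloTree(root=convert(dtree.seed_node))
    names = tree.leaf_names()
    if len(set(names)) != len(names):
        raise NewickParseError("duplicate leaf labels")
    return tree


def write_newick(tree: PhyloTree) -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            core = n.name or ""
        else:
            core = "(" + ",".join(fmt(c) for c in n.children) + ")" + (n.label or "")
        if n.parent is None:
            return core
        return f"{core}:{n.length!r}"

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Rooting and pruning

def _adjacency(tree: PhyloTree) -> dict[int, list[tuple[Node, float]]]:
    adj: dict[int, list[tuple[Node, float]]] = {}

    def walk(n: Node) -> None:
        for c in n.children:
            adj.setdefault(id(n), []).append((c, c.length))
            adj.setdefault(id(c), []).append((n, c.length))
            walk(c)

    walk(tree.root)
    return adj


def _paths_from(start: Node, adj) -> dict[int, tuple[float, list[Node]]]:
    """Distance and node path from ``start`` to every node (tree DFS)."""
    out: dict[int, tuple[float, list[Node]]] = {id(start): (0.0, [start])}
    stack = [start]
    seen = {id(start)}
    while stack:
        cur = stack.pop()
        d, path = out[id(cur)]
        for nb, w in adj.get(id(cur), []):
            if id(nb) in seen:
                continue
            seen.add(id(nb))
            out[id(nb)] = (d + w, path + [nb])
            stack.append(nb)
    return out


def _make_root(node: Node) -> None:
    """Reverse parent links so ``node`` becomes the root."""
    p = node.parent
    if p is None:
        return
    _make_root(p)
    p.children.remove(node)
    node.children.append(p)
    p.parent = node
    p.length = node.length
    node.parent = None
    node.length = 0.0


def _suppress_unary(tree: PhyloTree) -> None:
    """Merge internal nodes with exactly one child into their child."""

    def walk(n: Node) -> None:
        for c in list(n.children):
            walk(c)
        if n.parent is not None and len(n.children) == 1:
            child = n.children[0]
            child.length += n.length
            child.parent = n.parent
            n.parent.children[n.parent.children.index(n)] = child
    walk(tree.root)
    # root itself unary: promote the child
    while len(tree.root.children) == 1 and not tree.root.children[0].is_leaf:
        child = tree.root.children[0]
        child.parent = None
        child.length = 0.0
        tree.root = child


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root (a copy of) the tree at the midpoint of its longest
    leaf-to-leaf path.

    Ties between equally long paths are broken toward the lexicographically
    smallest (sorted) pair of endpoint names.  Total tree length is
    conserved, and a tree already rooted at its midpoint comes back
    metrically unchanged.
    """
    tree = tree.copy()
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise TreeStructureError("midpoint rooting needs at least two leaves")
    if tree.total_length() <= 0:
        raise TreeStructureError("all branch lengths are zero")
    adj = _adjacency(tree)

    best: tuple[float, tuple[str, str], list[Node]] | None = None
    for leaf in leaves:
        dists = _paths_from(leaf, adj)
        for other in leaves:
            if other is leaf:
                continue
            d, path = dists[id(other)]
            key = tuple(sorted((leaf.name or "", other.name or "")))
            if (
                best is None
                or d > best[0] + 1e-12
                or (abs(d - best[0]) <= 1e-12 and key < best[1])
            ):
                if path[0].name != key[0]:
                    path = list(reversed(path))
                best = (d, key, path)
    assert best is not None
    diameter, _, path = best
    half = diameter / 2.0

    # walk the path until the midpoint edge
    cum = 0.0
    for i in range(len(path) - 1):
        u, v = path[i], path[i + 1]
        w = v.length if v.parent is u else u.length  # edge length u-v
        if cum + w >= half - 1e-12:
            offset = half - cum  # distance from u along edge (u, v)
            break
        cum += w
    else:  # pragma: no cover - defensive
        raise RuntimeError("midpoint not found on path")

    # identify parent/child orientation of the edge
    if v.parent is u:
        parent_node, child_node = u, v
        offset_from_child = w - offset
    else:
        parent_node, child_node = v, u
        offset_from_child = offset

    if child_node.parent is tree.root and abs(
        offset_from_child - child_node.length
    ) <= 1e-12 and len(tree.root.children) == 2:
        return tree  # midpoint coincides with the current root

    # split the edge with a new root node
    new_root = Node(length=child_node.length - offset_from_child)
    parent_node.children[parent_node.children.index(child_node)] = new_root
    new_root.parent = parent_node
    new_root.add(child_node)
    child_node.length = offset_from_child
    _make_root(new_root)
    tree.root = new_root
    _suppress_unary(tree)
    return tree


def prune_zero_branches(tree: PhyloTree) -> tuple[PhyloTree, list[str]]:
    """Remove leaves whose terminal branch length is zero.

    Unary internal nodes left behind are suppressed with their lengths
    summed.  Returns the pruned tree and the removed leaf names.
    """
    tree = tree.copy()
    removed = [l.name or "" for l in tree.leaves() if l.length == 0.0]
    if not removed:
        return tree, []
    if tree.n_leaves - len(removed) < 2:
        raise TreeStructureError("pruning would leave fewer than two leaves")

    def walk(n: Node) -> None:
        for c in list(n.children):
            walk(c)
        n.children = [
            c for c in n.children if not (c.is_leaf and c.length == 0.0 and c.name)
        ]
    walk(tree.root)
    # drop internal nodes that lost all their leaves
    def drop_empty(n: Node) -> bool:
        n.children = [c for c in n.children if drop_empty(c)]
        return bool(n.children) or n.name is not None
    drop_empty(tree.root)
    _suppress_unary(tree)
    return tree, removed


# ---------------------------------------------------------------------------
# Contrasts

def pic_contrasts(
    tree: PhyloTree, traits: Mapping[str, float], trait_name: str = "trait"
) -> ContrastSet:
    """Felsenstein's independent contrasts for one trait.

    Requires a rooted, strictly bifurcating tree and a trait value for every
    leaf.  Returns n_leaves - 1 standardized contrasts in postorder, each
    tagged with an internal-node id.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise TreeStructureError("contrasts need at least two leaves")
    missing = [l.name for l in leaves if (l.name or "") not in traits]
    if missing:
        raise ValueError(f"missing trait values for leaves: {missing}")

    contrasts: list[tuple[str, float]] = []
    counter = {"i": 0}

    def rec(node: Node) -> tuple[float, float]:
        """Return (ancestral value, extended branch length v')."""
        if node.is_leaf:
            return float(traits[node.name or ""]), node.length
        if len(node.children) != 2:
            raise TreeStructureError(
                f"polytomy at internal node (degree {len(node.children)}); "
                "resolve the tree before computing contrasts"
            )
        (x1, v1) = rec(node.children[0])
        (x2, v2) = rec(node.children[1])
        vsum = v1 + v2
        if vsum <= 0:
            raise TreeStructureError(
                "zero combined branch length at a contrast; prune zero "
                "branches first"
            )
        counter["i"] += 1
        node_id = node.label or f"node{counter['i']}"
        contrasts.append((node_id, (x1 - x2) / math.sqrt(vsum)))
        anc = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2) if v1 > 0 and v2 > 0 else (
            x1 if v1 == 0 else x2
        )
        v_ext = node.length + (v1 * v2) / vsum
        return anc, v_ext

    rec(tree.root)
    return ContrastSet(trait=trait_name, contrasts=contrasts, n_leaves=len(leaves))


@dataclass
class OriginRegressionResult:
    slopes: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    n: int


def origin_regression(
    y: ContrastSet | np.ndarray,
    x: Mapping[str, ContrastSet | np.ndarray] | ContrastSet | np.ndarray,
) -> OriginRegressionResult:
    """No-intercept OLS of contrast responses on contrast predictors.

    R-squared is computed about zero, as appropriate for a through-origin
    model on contrasts.
    """
    yv = y.values() if isinstance(y, ContrastSet) else np.asarray(y, dtype=float)
    if isinstance(x, (ContrastSet, np.ndarray, list)):
        x = {"x": x}
    cols = {
        k: (v.values() if isinstance(v, ContrastSet) else np.asarray(v, dtype=float))
        for k, v in x.items()
    }
    X = np.column_stack(list(cols.values()))
    if X.shape[0] != yv.shape[0]:
        raise ValueError("contrast counts do not match")
    if X.shape[0] < 2:
        raise ValueError("need at least two contrasts")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular contrast design")
    fit = sm.OLS(yv, X).fit()
    names = list(cols)
    return OriginRegressionResult(
        slopes={n: float(b) for n, b in zip(names, fit.params)},
        pvalues={n: float(p) for n, p in zip(names, fit.pvalues)},
        r_squared=float(fit.rsquared),  # uncentered for no-intercept model
        n=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# Brownian-motion simulation

def simulate_bm(
    tree: PhyloTree,
    rate: float,
    seed: int | np.random.Generator,
    root_value: float = 0.0,
    coupled_slope: float | None = None,
    coupled_resid_rate: float = 0.0,
    coupled_root_value: float = 0.0,
) -> dict[str, float] | tuple[dict[str, float], dict[str, float]]:
    """Simulate Brownian-motion trait evolution on the tree.

    Each branch contributes a Gaussian increment with variance
    ``rate * branch_length``.  With ``coupled_slope`` set, a second trait is
    co-simulated whose increments are ``slope`` times the first trait's
    increments plus independent BM noise of variance rate
    ``coupled_resid_rate``; the pair is returned as ``(x_traits, y_traits)``.
    """
    if rate < 0 or coupled_resid_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xvals: dict[str, float] = {}
    yvals: dict[str, float] = {}

    def walk(node: Node, x: float, yv: float) -> None:
        for c in node.children:
            dx = rng.normal(0.0, math.sqrt(rate * c.length)) if rate * c.length > 0 else 0.0
            cx = x + dx
            cy = yv
            if coupled_slope is not None:
                noise_var = coupled_resid_rate * c.length
                cy = yv + coupled_slope * dx + (
                    rng.normal(0.0, math.sqrt(noise_var)) if noise_var > 0 else 0.0
                )
            if c.is_leaf:
                xvals[c.name or ""] = cx
                if coupled_slope is not None:
                    yvals[c.name or ""] = cy
            walk(c, cx, cy)

    walk(tree.root, root_value, coupled_root_value)
    if coupled_slope is not None:
        return xvals, yvals
    return xvals
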