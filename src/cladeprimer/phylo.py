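"""Distances, neighbor-joining, bootstrap support, monophyly, and iterative
phylogeny-based collection of target-taxon sequences.

Distances are Jukes-Cantor (JC) corrected proportions of differing sites,
d = -(3/4) ln(1 - (4/3) p), computed with pairwise deletion: only columns in
which both sequences carry a concrete base (A/C/G/T) are compared.  Saturated
pairs (p >= 3/4, where the JC correction diverges) are capped at a configured
distance and flagged rather than dropped, so distant-phylum pairs stay usable
inside matrices.

The collection algorithm grows a target sequence set from a labelled backbone:
queries are added in batches, and within each batch a bootstrapped NJ tree is
rebuilt repeatedly; any query falling in a well-supported clade that contains
at least one seed (or previously collected) target sequence and no backbone
non-target sequence is collected, collected queries are removed from the
working set, and the inner loop repeats until no further query qualifies.
Queries that are never collected and whose replicate-to-replicate placement
among backbone phyla is unstable are reported as unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seq_io import Alignment, SequenceRecord

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "TreeNode",
    "Tree",
    "p_distance",
    "jc_distance",
    "jc_from_p_array",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "is_monophyletic",
    "CollectionParams",
    "CollectionResult",
    "iterative_collect",
]

JC_SATURATION = 0.75


class SaturationError(ValueError):
    """p >= 3/4: the JC correction is undefined (multiple-hit saturation)."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_CONCRETE_BITS = (1, 2, 4, 8)


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Proportion of differing sites under pairwise deletion.

    Returns ``(p, n_compared)``.  Columns where either sequence has a gap or a
    degenerate code are excluded from numerator and denominator.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    from .seq_io import encode_bits

    x, y = encode_bits(a), encode_bits(b)
    both = np.isin(x, _CONCRETE_BITS) & np.isin(y, _CONCRETE_BITS)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no comparable columns (pairwise deletion removed all)")
    diff = int((x[both] != y[both]).sum())
    return diff / n, n


def jc_distance(p: float) -> float:
    """JC-corrected substitutions/site for an observed mismatch proportion."""
    if not 0.0 <= p < JC_SATURATION:
        if p >= JC_SATURATION:
            raise SaturationError(f"p = {p} >= 3/4: JC distance undefined")
        raise ValueError(f"p must be in [0, 0.75), got {p}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_from_p_array(p: np.ndarray, cap: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised JC correction; saturated entries are capped and flagged."""
    sat = p >= JC_SATURATION
    d = np.empty_like(p, dtype=float)
    ok = ~sat
    d[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    d[sat] = cap
    return d, sat


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric JC distance matrix with per-pair saturation flags."""

    labels: tuple[str, ...]
    d: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self), 1)
        return self.d[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        sat = None if self.saturated is None else self.saturated[np.ix_(idx, idx)]
        return DistanceMatrix(tuple(labels), self.d[np.ix_(idx, idx)], sat)


def _p_matrix(bits: np.ndarray) -> np.ndarray:
    """Pairwise-deletion p-distance matrix from a 4-bit code matrix."""
    n, L = bits.shape
    onehot = np.stack([(bits == b) for b in _CONCRETE_BITS], axis=-1)
    A = onehot.reshape(n, L * 4).astype(np.float32)
    matches = A @ A.T
    mask = onehot.any(axis=-1).astype(np.float32)
    comparable = mask @ mask.T
    off = ~np.eye(n, dtype=bool)
    if (comparable[off] < 1).any():
        i, j = np.argwhere((comparable < 1) & off)[0]
        raise ValueError(f"no comparable columns between rows {i} and {j}")
    with np.errstate(invalid="ignore"):
        p = 1.0 - matches / comparable
    np.fill_diagonal(p, 0.0)
    return np.clip(p.astype(float), 0.0, 1.0)


def distance_matrix(alignment: Alignment, cap: float = 5.0) -> DistanceMatrix:
    """JC distance matrix over an alignment (pairwise deletion, saturation cap)."""
    p = _p_matrix(alignment.bit_matrix())
    d, sat = jc_from_p_array(p, cap=cap)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrise away float32 rounding noise
    return DistanceMatrix(tuple(alignment.ids), d, sat)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class TreeNode:
    """Tree node; ``length`` is the branch to the parent, ``support`` the
    bootstrap percentage of that branch's bipartition (internal edges only)."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float = 0.0,
        support: float | None = None,
        children: Iterable["TreeNode"] = (),
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        for c in children:
            self.add_child(c)

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.postorder() if n.is_tip)


class Tree:
    """A phylogenetic tree.  NJ output is unrooted and represented with a
    trifurcating root node."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    def postorder(self) -> Iterable[TreeNode]:
        return self.root.postorder()

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def find_tip(self, name: str) -> TreeNode:
        for t in self.tips():
            if t.name == name:
                return t
        raise KeyError(f"tip {name!r} not in tree")

    # -- bipartitions ------------------------------------------------------

    def bipartitions(self, with_support: bool = False):
        """Non-trivial bipartitions as canonical frozensets of tip names (the
        side not containing the lexicographically first tip)."""
        full = self.tip_names()
        ref = min(full)
        out = {} if with_support else set()
        leafsets: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                leafsets[id(node)] = frozenset([node.name])
                continue
            ls = frozenset().union(*(leafsets[id(c)] for c in node.children))
            leafsets[id(node)] = ls
            if node is self.root or len(ls) < 2 or len(full - ls) < 2:
                continue
            side = full - ls if ref in ls else ls
            if with_support:
                out[side] = node  # type: ignore[index]
            else:
                out.add(side)  # type: ignore[union-attr]
        return out

    # -- distances ---------------------------------------------------------

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Path-length distances between all tips (O(n^2))."""
        tips = self.tips()
        index = {id(t): i for i, t in enumerate(tips)}
        n = len(tips)
        D = np.zeros((n, n))
        below: dict[int, list[tuple[int, float]]] = {}
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = [(index[id(node)], 0.0)]
                continue
            kids = [
                [(i, d + c.length) for i, d in below.pop(id(c))] for c in node.children
            ]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i, di in kids[a]:
                        for j, dj in kids[b]:
                            D[i, j] = D[j, i] = di + dj
            below[id(node)] = [x for k in kids for x in k]
        return [t.name for t in tips], D

    # -- rerooting ---------------------------------------------------------

    def _adjacency(self):
        adj: dict[int, list[tuple[TreeNode, float, float | None]]] = {}
        nodes: dict[int, TreeNode] = {}
        for node in self.postorder():
            nodes[id(node)] = node
            adj.setdefault(id(node), [])
            if node.parent is not None:
                adj[id(node)].append((node.parent, node.length, node.support))
                adj.setdefault(id(node.parent), []).append(
                    (node, node.length, node.support)
                )
        return adj

    def rooted_on_edge(self, child: TreeNode, dist_from_child: float) -> "Tree":
        """Root the tree on the edge above ``child``; supports stay with the
        subtree they subtend."""
        if child.parent is None:
            raise ValueError("cannot root above the current root")
        adj = self._adjacency()

        def build(node: TreeNode, come_from: TreeNode, length: float, support) -> TreeNode:
            nn = TreeNode(name=node.name, length=length, support=support)
            for nbr, l, s in adj[id(node)]:
                if nbr is not come_from:
                    nn.add_child(build(nbr, node, l, s))
            return nn

        total = child.length
        upper = max(total - dist_from_child, 0.0)
        root = TreeNode()
        root.add_child(build(child, child.parent, dist_from_child, child.support))
        root.add_child(build(child.parent, child, upper, child.support))
        return Tree(root)

    def rooted_at_outgroup(self, outgroup: str) -> "Tree":
        tip = self.find_tip(outgroup)
        return self.rooted_on_edge(tip, tip.length / 2.0)

    def rooted_at_midpoint(self) -> "Tree":
        names, D = self.tip_distance_matrix()
        i, j = np.unravel_index(np.argmax(D), D.shape)
        if D[i, j] == 0.0:
            # all tips identical: root arbitrarily above the first tip
            tip = self.find_tip(names[0])
            return self.rooted_on_edge(tip, tip.length / 2.0)
        half = D[i, j] / 2.0
        # walk from tip i toward tip j until the midpoint falls inside an edge
        path = self._path(names[i], names[j])
        acc = 0.0
        for node, edge_len, downward in path:
            if acc + edge_len >= half:
                rem = half - acc
                dist_from_child = rem if downward else edge_len - rem
                return self.rooted_on_edge(node, min(max(dist_from_child, 0.0), edge_len))
            acc += edge_len
        return self.rooted_on_edge(path[-1][0], path[-1][1] / 2.0)

    def _path(self, a: str, b: str):
        """Edges from tip ``a`` to tip ``b`` as (child_node, length, walking_up)."""
        ta, tb = self.find_tip(a), self.find_tip(b)
        anc_a, node = [], ta
        while node is not None:
            anc_a.append(node)
            node = node.parent
        anc_b, node = [], tb
        in_a = {id(n) for n in anc_a}
        while id(node) not in in_a:
            anc_b.append(node)
            node = node.parent
        lca = node
        up = [(n, n.length, True) for n in anc_a[: anc_a.index(lca)]]
        down = [(n, n.length, False) for n in reversed(anc_b)]
        return up + down

    # -- output ------------------------------------------------------------

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.6f}"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining tree (Saitou & Nei / Studier-Keppler form).

    Deterministic: ties in the Q criterion are broken toward the lowest index
    pair.  Negative branch-length estimates are clamped to zero with the
    deficit transferred to the sister branch, preserving the path length
    between the joined nodes.
    """
    n0 = len(dm)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    D = dm.d.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), n)  # row-major argmin -> lowest (i, j)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        parent = TreeNode(children=[ni, nj_])
        dnew = np.maximum(0.5 * (D[i, :] + D[j, :] - dij), 0.0)
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        last = np.append(dnew[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return Tree(TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _bootstrap_trees(
    bits: np.ndarray,
    labels: Sequence[str],
    n_reps: int,
    rng: np.random.Generator,
    cap: float,
) -> tuple[list[Tree], int]:
    """NJ trees on column-resampled replicates; invalid replicates skipped."""
    n, L = bits.shape
    trees: list[Tree] = []
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        try:
            p = _p_matrix(bits[:, cols])
        except ValueError:
            skipped += 1
            continue
        d, _ = jc_from_p_array(p, cap=cap)
        np.fill_diagonal(d, 0.0)
        trees.append(nj_tree(DistanceMatrix(tuple(labels), (d + d.T) / 2.0)))
    return trees, skipped


def _annotate_support(tree: Tree, replicates: list[Tree]) -> None:
    counts: dict[frozenset[str], int] = {}
    for rep in replicates:
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    denom = max(len(replicates), 1)
    for bp, node in tree.bipartitions(with_support=True).items():
        node.support = 100.0 * counts.get(bp, 0) / denom


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 100,
    rng_seed: int | np.random.Generator = 0,
    cap: float = 5.0,
    return_replicates: bool = False,
):
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; support is the
    percentage of valid replicates containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    tree = nj_tree(distance_matrix(alignment, cap=cap))
    reps, skipped = _bootstrap_trees(
        alignment.bit_matrix(), alignment.ids, n_reps, rng, cap
    )
    _annotate_support(tree, reps)
    if return_replicates:
        return tree, reps, skipped
    return tree


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------


def is_monophyletic(
    tree: Tree, tips: Iterable[str], outgroup: str | None = None
) -> tuple[bool, float | None]:
    """Whether ``tips`` form exactly one clade of the (rooted) tree.

    The tree is rooted at ``outgroup`` if given, else at its midpoint.
    Returns ``(monophyletic, support)`` where support is the clade's bootstrap
    value when available.
    """
    tipset = frozenset(tips)
    known = tree.tip_names()
    unknown = tipset - known
    if unknown:
        raise KeyError(f"unknown tip id(s): {sorted(unknown)[:5]}")
    rooted = (
        tree.rooted_at_outgroup(outgroup) if outgroup else tree.rooted_at_midpoint()
    )
    if len(tipset) == 1:
        return True, None
    leafsets: dict[int, frozenset[str]] = {}
    for node in rooted.postorder():
        if node.is_tip:
            leafsets[id(node)] = frozenset([node.name])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.children)
            )
        if leafsets[id(node)] == tipset:
            return True, node.support
    return False, None


# ---------------------------------------------------------------------------
# iterative collection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollectionParams:
    """Parameters of the iterative target-sequence collection."""

    batch_size: int = 500
    support_threshold: float = 80.0
    bootstrap_reps: int = 100
    rng_seed: int = 0
    outgroup_id: str | None = None
    #: a never-collected query is 'unclassified' when no single backbone phylum
    #: attracts it in at least this fraction of bootstrap replicates
    stability_threshold: float = 0.5
    saturation_cap: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.support_threshold <= 100:
            raise ValueError("support_threshold must be in (0, 100]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class RoundRecord:
    batch: int
    round: int
    collected: tuple[str, ...]
    clade_supports: tuple[float, ...]


@dataclass(frozen=True)
class CollectionResult:
    """Outcome of iterative collection: a partition of the query ids."""

    target_ids: frozenset[str]
    nontarget_ids: frozenset[str]
    unclassified_ids: frozenset[str]
    rounds: tuple[RoundRecord, ...]
    batch_monophyly: tuple[float | None, ...]
    final_monophyly_support: float | None

    def audit_tsv(self) -> str:
        lines = ["batch\tround\tn_collected\tmin_clade_support\tids"]
        for r in self.rounds:
            sup = f"{min(r.clade_supports):.1f}" if r.clade_supports else ""
            lines.append(
                f"{r.batch}\t{r.round}\t{len(r.collected)}\t{sup}\t{','.join(r.collected)}"
            )
        return "\n".join(lines) + "\n"


def _chunks(seq: list, size: int):
    for i in range(0, len(seq), size):
        yield seq[i : i + size]


def iterative_collect(
    backbone: Alignment,
    queries: Alignment | Sequence[SequenceRecord],
    target_taxon: str,
    params: CollectionParams = CollectionParams(),
) -> CollectionResult:
    """Collect query sequences related to ``target_taxon`` by repeated
    bootstrapped NJ tree construction against a labelled backbone.

    ``backbone`` must contain at least one seed sequence labelled with the
    target taxon and at least one non-target reference; the outgroup (used for
    rooting) is named in ``params.outgroup_id``.  Queries are unlabelled and
    must share the backbone's alignment columns.
    """
    qrecords = list(queries.records if isinstance(queries, Alignment) else queries)
    qids = [r.id for r in qrecords]
    if set(qids) & set(backbone.ids):
        raise ValueError("queries must be disjoint from the backbone")

    def is_target(r: SequenceRecord) -> bool:
        return r.taxon_label is not None and (
            r.taxon_label == target_taxon
            or r.taxon_label.startswith(target_taxon + "/")
        )

    outgroup = params.outgroup_id
    seeds = {r.id for r in backbone if is_target(r)}
    nontargets = {
        r.id for r in backbone if not is_target(r) and r.id != outgroup
    }
    if not seeds:
        raise ValueError(
            f"backbone contains no seed sequence for target {target_taxon!r}"
        )
    if not nontargets:
        raise ValueError("backbone contains no non-target reference sequence")

    combined = Alignment(tuple(backbone.records) + tuple(qrecords))
    phylum_of = {
        r.id: (r.phylum or "?") for r in backbone if r.id != outgroup
    }
    rng = np.random.default_rng(params.rng_seed)

    collected_all: set[str] = set()
    unclassified: set[str] = set()
    rounds: list[RoundRecord] = []
    batch_monophyly: list[float | None] = []

    for b_idx, batch in enumerate(_chunks(qids, params.batch_size)):
        batch_set = set(batch)
        working = list(backbone.ids) + batch
        batch_collected: set[str] = set()
        j = 0
        last_reps: list[Tree] = []
        while True:
            j += 1
            sub = combined.subset(working)
            tree, reps, _ = bootstrap_support(
                sub,
                n_reps=params.bootstrap_reps,
                rng_seed=rng,
                cap=params.saturation_cap,
                return_replicates=True,
            )
            last_reps = reps
            rooted = (
                tree.rooted_at_outgroup(outgroup)
                if outgroup and outgroup in set(working)
                else tree.rooted_at_midpoint()
            )
            anchors = seeds | batch_collected | (collected_all & set(working))
            m: set[str] = set()
            supports: list[float] = []
            leafsets: dict[int, frozenset[str]] = {}
            for node in rooted.postorder():
                if node.is_tip:
                    leafsets[id(node)] = frozenset([node.name])
                    continue
                ls = frozenset().union(*(leafsets[id(c)] for c in node.children))
                leafsets[id(node)] = ls
                if node.support is None or node.support <= params.support_threshold:
                    continue
                if ls & nontargets:
                    continue
                if not ls & anchors:
                    continue
                new = (ls & batch_set) - batch_collected
                if new:
                    m |= new
                    supports.append(node.support)
            rounds.append(
                RoundRecord(b_idx, j, tuple(sorted(m)), tuple(sorted(supports)))
            )
            if not m:
                break
            batch_collected |= m
            working = [w for w in working if w not in m]

        # re-verify monophyly of the batch's collected set plus seeds
        if batch_collected:
            ci = list(backbone.ids) + batch
            tree_ci = bootstrap_support(
                combined.subset(ci),
                n_reps=params.bootstrap_reps,
                rng_seed=rng,
                cap=params.saturation_cap,
            )
            _, supp = is_monophyletic(
                tree_ci, seeds | batch_collected, outgroup=outgroup
            )
            batch_monophyly.append(supp)
        else:
            batch_monophyly.append(None)
        collected_all |= batch_collected

        # stability of never-collected queries across the final round's replicates
        uncollected = batch_set - batch_collected
        if uncollected and last_reps:
            votes: dict[str, dict[str, int]] = {q: {} for q in uncollected}
            for rep in last_reps:
                names, D = rep.tip_distance_matrix()
                idx = {nm: k for k, nm in enumerate(names)}
                bb = [nm for nm in names if nm in phylum_of]
                bb_idx = np.array([idx[nm] for nm in bb])
                for q in uncollected:
                    if q not in idx:
                        continue
                    nearest = bb[int(np.argmin(D[idx[q], bb_idx]))]
                    ph = phylum_of[nearest]
                    votes[q][ph] = votes[q].get(ph, 0) + 1
            for q, v in votes.items():
                total = sum(v.values())
                if not total or max(v.values()) / total < params.stability_threshold:
                    unclassified.add(q)

    # final monophyly of all collected targets plus seeds on the combined tree
    final_support: float | None = None
    if collected_all:
        final_ids = list(backbone.ids) + sorted(collected_all)
        tree_fin = bootstrap_support(
            combined.subset(final_ids),
            n_reps=params.bootstrap_reps,
            rng_seed=rng,
            cap=params.saturation_cap,
        )
        _, final_support = is_monophyletic(
            tree_fin, seeds | collected_all, outgroup=outgroup
        )

    target_ids = frozenset(seeds | collected_all)
    nontarget_ids = frozenset(set(qids) - collected_all - unclassified)
    return CollectionResult(
        target_ids=target_ids,
        nontarget_ids=nontarget_ids,
        unclassified_ids=frozenset(unclassified),
        rounds=tuple(rounds),
        batch_monophyly=tuple(batch_monophyly),
        final_monophyly_support=final_support,
    )
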