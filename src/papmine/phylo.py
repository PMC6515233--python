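"""Poisson-corrected distances, neighbor joining, bootstrap, group labels.

Distances between aligned protein sequences use the Poisson correction
d = -ln(1 - p), where p is the observed proportion of differing residues
over the comparable sites; pairwise deletion drops, per pair, exactly the
columns where either member has a gap or an X.  Trees are built with the
Saitou-Nei neighbor-joining agglomeration, which recovers additive
distance matrices exactly; branch supports come from column-resampling
bootstrap replicates.  Queries are assigned to phylogenetic groups
(I-IV in the PAP family) by the smallest surrounding clade whose
user-supplied anchor sequences carry a unanimous label.

Determinism contracts: Q-matrix ties are broken by the lexicographically
smallest cluster-id pair, and the bootstrap is driven by a caller-supplied
seed, so identical inputs give bit-identical trees and supports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .seqio import AlignedSet, GAP

EXCLUDED = {GAP, "X"}


class PhyloError(ValueError):
    """Raised for degenerate distance inputs (no comparable sites, saturation)."""


def poisson_distance(a: str, b: str) -> tuple[float, int]:
    """Poisson-corrected distance and the number of comparable sites.

    Returns (+inf, n) when p >= 1 (saturated pair); raises PhyloError when
    no site is comparable.
    """
    if len(a) != len(b):
        raise PhyloError("aligned sequences must have equal length")
    n = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in EXCLUDED or y in EXCLUDED:
            continue
        n += 1
        if x != y:
            mismatches += 1
    if n == 0:
        raise PhyloError("zero comparable sites")
    p = mismatches / n
    if p >= 1.0:
        return math.inf, n
    return (-math.log1p(-p) if p > 0 else 0.0), n


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    d: np.ndarray  # symmetric, zero diagonal; +inf marks saturated pairs
    comparable: np.ndarray  # per-pair comparable site counts

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.comparable.shape != (n, n):
            raise PhyloError("matrix shape does not match ids")
        if not np.array_equal(self.d, self.d.T):
            raise PhyloError("distance matrix must be symmetric")
        if np.any(np.diagonal(self.d) != 0):
            raise PhyloError("diagonal must be zero")

    @property
    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isinf(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for i, name in enumerate(self.ids):
            vals = "\t".join(f"{self.d[i, j]:.6g}" for j in range(len(self.ids)))
            lines.append(f"{name}\t{vals}")
        return "\n".join(lines) + "\n"


def build_distance_matrix(alignment: AlignedSet) -> DistanceMatrix:
    ids = tuple(alignment.ids)
    if len(ids) < 3:
        raise PhyloError("need at least 3 sequences")
    seqs = [s for _, s in alignment.records]
    n = len(ids)
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    failures = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij, nij = poisson_distance(seqs[i], seqs[j])
            except PhyloError:
                failures.append((ids[i], ids[j]))
                continue
            d[i, j] = d[j, i] = dij
            comp[i, j] = comp[j, i] = nij
    if failures:
        raise PhyloError(f"pairs with zero comparable sites: {failures}")
    return DistanceMatrix(ids=ids, d=d, comparable=comp)


@dataclass
class PhyloTree:
    """An unrooted tree with non-negative branch lengths and % supports.

    Wraps a dendropy tree (trifurcating at the seed node, the standard
    unrooted representation).  Negative neighbor-joining length estimates
    are clamped to zero; the raw estimate is kept in ``raw_lengths``.
    """

    tree: dendropy.Tree
    raw_lengths: dict = field(default_factory=dict)  # bipartition -> raw estimate
    supports: dict = field(default_factory=dict)  # bipartition -> percent

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def _leafsets(self):
        """Postorder map node -> frozenset of leaf labels beneath it."""
        sets = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                sets[node] = frozenset([node.taxon.label])
            else:
                sets[node] = frozenset().union(
                    *(sets[c] for c in node.child_nodes())
                )
        return sets

    def _canonical(self, side: frozenset, all_leaves: frozenset) -> frozenset:
        ref = min(all_leaves)
        return all_leaves - side if ref in side else side

    def bipartitions(self) -> set:
        """Non-trivial splits, each as the canonical (reference-free) side."""
        sets = self._leafsets()
        all_leaves = frozenset(self.leaf_labels)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = sets[node]
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(self._canonical(side, all_leaves))
        return out

    def path_length_matrix(self) -> tuple[tuple, np.ndarray]:
        """Leaf-to-leaf patristic distances (ids sorted)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        ids = tuple(sorted(t.label for t in self.tree.taxon_namespace))
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(ids)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
        return ids, m

    def annotate_supports(self, supports: Mapping[frozenset, float]) -> None:
        """Attach percent supports to the matching internal nodes."""
        self.supports = dict(supports)
        sets = self._leafsets()
        all_leaves = frozenset(self.leaf_labels)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            key = self._canonical(sets[node], all_leaves)
            if key in self.supports:
                node.label = f"{self.supports[key]:g}"

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster id, cluster id) pair, where a cluster's id is the smallest
    leaf label it contains.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise PhyloError(
            "distance matrix has saturated (+inf) pairs; remove or re-align "
            f"the offending sequences: {dm.saturated_pairs}"
        )

    taxa = dendropy.TaxonNamespace(list(dm.ids))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # smallest leaf label per active cluster
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        keys.append(label)
    dist = {
        (i, j): float(dm.d[i, j]) for i in range(n0) for j in range(n0) if i < j
    }
    active = list(range(n0))
    next_idx = n0
    raw_lengths: dict = {}
    clamped: list[tuple] = []

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    def setd(i: int, j: int, v: float) -> None:
        dist[(i, j) if i < j else (j, i)] = v

    def attach(parent: dendropy.Node, child_i: int, length: float) -> None:
        child = nodes[child_i]
        parent.add_child(child)
        child.edge.length = max(0.0, length)
        if length < 0:
            clamped.append((keys[child_i], length))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = get(i, j)
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        parent = dendropy.Node()
        attach(parent, i, bi)
        attach(parent, j, bj)
        nodes.append(parent)
        new_key = min(keys[i], keys[j])
        keys.append(new_key)
        u = next_idx
        next_idx += 1
        for k in active:
            if k in (i, j):
                continue
            setd(u, k, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    # final three clusters join at the unrooted tree's central node
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    for k, lk in ((a, la), (b, lb), (c, lc)):
        attach(root, k, lk)
    tree.seed_node = root
    tree.update_taxon_namespace()

    pt = PhyloTree(tree=tree)
    if clamped:
        all_leaves = frozenset(pt.leaf_labels)
        sets = pt._leafsets()
        raw_by_key = dict(clamped)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            key = min(sets[node])
            if key in raw_by_key and node.edge.length == 0.0:
                raw_lengths[pt._canonical(sets[node], all_leaves)] = raw_by_key[key]
    pt.raw_lengths = raw_lengths
    return pt


def resample_columns(alignment: AlignedSet, rng: np.random.Generator) -> AlignedSet:
    cols = rng.integers(0, alignment.length, size=alignment.length)
    return AlignedSet(
        records=tuple(
            (rec_id, "".join(seq[c] for c in cols))
            for rec_id, seq in alignment.records
        )
    )


def bootstrap_support(
    alignment: AlignedSet,
    n_reps: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree of the full alignment with bootstrap percent supports.

    Columns are resampled with replacement; each replicate's tree is built
    with the same distance + NJ pipeline; a replicate whose distance matrix
    degenerates (zero-comparable or saturated pair) is dropped and counted,
    with a warning if more than 10% are lost.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = neighbor_joining(build_distance_matrix(alignment))
    focal = full.bipartitions()
    counts = {bp: 0 for bp in focal}
    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(n_reps):
        rep = resample_columns(alignment, rng)
        try:
            rep_tree = neighbor_joining(build_distance_matrix(rep))
        except PhyloError:
            dropped += 1
            continue
        rep_bps = rep_tree.bipartitions()
        for bp in focal:
            if bp in rep_bps:
                counts[bp] += 1
    kept = n_reps - dropped
    if dropped > 0.1 * n_reps:
        warnings.warn(
            f"{dropped}/{n_reps} bootstrap replicates dropped (degenerate pairs)",
            stacklevel=2,
        )
    if kept == 0:
        raise PhyloError("every bootstrap replicate was degenerate")
    full.annotate_supports({bp: 100.0 * c / kept for bp, c in counts.items()})
    return full


@dataclass(frozen=True)
class GroupAssignment:
    labels: dict  # id -> group label ("unresolved" when no unanimous clade)
    anchors: dict  # reference id -> known label


def assign_groups(tree: PhyloTree, anchors: Mapping[str, str]) -> GroupAssignment:
    """Label each query leaf by its smallest unanimous anchor-bearing clade.

    On an unrooted tree a "clade" is either side of an edge; for a query q
    we take, over all sides containing q and at least one anchor, the
    smallest side whose anchors all share one label.  No such side, or
    conflicting minimal sides, leaves q "unresolved".
    """
    leaves = set(tree.leaf_labels)
    missing = [a for a in anchors if a not in leaves]
    if missing:
        raise PhyloError(f"anchor ids absent from tree: {sorted(missing)}")

    sets = tree._leafsets()
    all_leaves = frozenset(leaves)
    sides = set()
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        s = frozenset(sets[node])
        sides.add(s)
        sides.add(all_leaves - s)
    sides.add(all_leaves)

    labels = {}
    for q in sorted(leaves):
        if q in anchors:
            labels[q] = anchors[q]
            continue
        candidates = []
        for s in sides:
            if q not in s:
                continue
            present = {anchors[a] for a in s if a in anchors}
            if len(present) == 1:
                candidates.append((len(s), present.pop()))
        if not candidates:
            labels[q] = "unresolved"
            continue
        best_size = min(c[0] for c in candidates)
        best_labels = {lab for size, lab in candidates if size == best_size}
        labels[q] = best_labels.pop() if len(best_labels) == 1 else "unresolved"
    return GroupAssignment(labels=labels, anchors=dict(anchors))


def read_anchor_table(path) -> dict:
    """Anchors TSV: id <tab> label."""
    anchors = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rec_id, _, label = line.partition("\t")
            anchors[rec_id] = label
    return anchors
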