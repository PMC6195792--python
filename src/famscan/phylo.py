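"""Poisson-corrected distances, neighbor joining, bootstrap, groups.

The tree pipeline mirrors a classic distance-based protein phylogeny:
pairwise Poisson-corrected distances ``d = -ln(1 - p)`` (p = proportion
of differing sites under pairwise deletion of gap columns), Saitou-Nei
neighbor joining on the distance matrix, nonparametric bootstrap over
alignment columns for internal-edge supports, and reference-guided
clade labelling (the CNGC literature's Groups I, II, III, IVa, IVb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .records import ProteinRecord

SATURATION_P = 1.0 - 1e-12


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    saturated_pairs: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(
            self.matrix[self.taxa.index(a), self.taxa.index(b)]
        )


def _check_msa(msa: list[ProteinRecord]) -> int:
    if len(msa) < 2:
        raise ValueError("alignment needs at least 2 rows")
    lengths = {len(r.sequence) for r in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    return lengths.pop()


class AlignedProtein(ProteinRecord):
    """Protein record that may carry '-' gap characters."""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        from .records import PROTEIN_ALPHABET

        bad = set(self.sequence) - PROTEIN_ALPHABET - {"-"}
        if bad:
            raise ValueError(
                f"aligned record {self.id!r} has invalid letters {sorted(bad)}"
            )


def poisson_distance(msa: list[ProteinRecord]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances with pairwise deletion.

    For each pair, columns where either row has a gap are dropped;
    p = differing / compared sites and d = -ln(1 - p).  A pair with p
    at or beyond saturation is flagged and given an infinite distance;
    a pair with zero comparable columns is an error naming the pair.
    """
    _check_msa(msa)
    n = len(msa)
    taxa = [r.id for r in msa]
    if len(set(taxa)) != n:
        raise ValueError("duplicate taxon ids in alignment")
    D = np.zeros((n, n))
    saturated = set()
    for i in range(n):
        si = msa[i].sequence
        for j in range(i + 1, n):
            sj = msa[j].sequence
            compared = diffs = 0
            for a, b in zip(si, sj):
                if a == "-" or b == "-":
                    continue
                compared += 1
                if a != b:
                    diffs += 1
            if compared == 0:
                raise ValueError(
                    f"zero comparable sites for pair ({taxa[i]}, {taxa[j]})"
                )
            p = diffs / compared
            if p >= SATURATION_P:
                saturated.add(frozenset((taxa[i], taxa[j])))
                d = math.inf
            else:
                d = -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(taxa, D, saturated)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken by the
    lexicographically smallest (representative-leaf) taxon pair.
    Negative branch lengths are clamped to zero with the deficit moved
    to the sibling edge.  Returns an unrooted tree (trifurcating seed
    node) over the input taxa.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxon_ns = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    reps: dict[str, str] = {}  # cluster key -> smallest contained leaf name
    active = list(dm.taxa)
    dist = {
        (a, b): float(dm.matrix[i, j])
        for i, a in enumerate(dm.taxa)
        for j, b in enumerate(dm.taxa)
    }
    for name in dm.taxa:
        node = dendropy.Node()
        node.taxon = taxon_ns.new_taxon(name)
        nodes[name] = node
        reps[name] = name

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)]

    counter = 0
    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * d(a, b) - rowsum[a] - rowsum[b]
                key = tuple(sorted((reps[a], reps[b])))
                cand = (q, key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        la = d(a, b) / 2.0 + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lb = d(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        new_key = f"__cluster{counter}"
        counter += 1
        nodes[new_key] = parent
        reps[new_key] = min(reps[a], reps[b])
        for c in active:
            if c in (a, b):
                continue
            duc = (d(a, c) + d(b, c) - d(a, b)) / 2.0
            dist[(new_key, c)] = dist[(c, new_key)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)]
        active.append(new_key)
        active.sort(key=lambda c: reps[c])
    # connect the final three clusters to one internal node
    a, b, c = sorted(active, key=lambda x: reps[x])
    root = dendropy.Node()
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2.0
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2.0
    for name, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[name])
        nodes[name].edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> dict:
    """Internal-edge bipartitions as canonical frozensets of leaf names.

    Each internal edge is keyed by the leaf set on its child side,
    canonicalized to the side *not* containing the overall smallest
    leaf name (so the encoding is rooting-invariant).  Maps
    bipartition -> child node.
    """
    leaves = sorted(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    all_set = frozenset(leaves)
    ref = leaves[0]
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue  # trivial split
        side = all_set - below if ref in below else below
        out[side] = node
    return out


def bootstrap_support(
    msa: list[ProteinRecord], n_reps: int = 1000, seed: int = 0
) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the full-data tree is the
    percentage of replicate trees containing the same bipartition,
    written as an integer internal-node label.  Fully reproducible for
    a fixed seed, and invariant to the input row order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ncols = _check_msa(msa)
    msa = sorted(msa, key=lambda r: r.id)
    full_tree = nj_tree(poisson_distance(msa))
    target = _bipartitions(full_tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.RandomState(seed)
    for _ in range(n_reps):
        cols = rng.randint(0, ncols, size=ncols)
        rep_msa = [
            AlignedProtein(r.id, "".join(r.sequence[c] for c in cols))
            for r in msa
        ]
        try:
            rep_tree = nj_tree(poisson_distance(rep_msa))
        except ValueError:
            continue  # saturated/degenerate replicate contributes nothing
        rep_bps = set(_bipartitions(rep_tree))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in target.items():
        support = round(100.0 * counts[bp] / n_reps)
        node.label = str(int(support))
    return full_tree


@dataclass
class GroupAssignment:
    groups: dict[str, str]  # leaf -> group label, "unplaced" on conflict


def assign_groups(
    tree: dendropy.Tree, references: dict[str, str]
) -> GroupAssignment:
    """Label query leaves with the group of their smallest unanimous clade.

    ``references`` maps reference leaf names to group labels.  Each
    unlabeled leaf takes the group of the smallest bipartition side
    containing it that contains at least one reference; if that side's
    references disagree the leaf is flagged ``unplaced``.
    """
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(references) - leaf_names)
    if missing:
        raise ValueError(f"reference leaves missing from tree: {missing}")
    all_set = frozenset(leaf_names)
    sides = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        sides.add(below)
        sides.add(all_set - below)
    ordered = sorted(sides, key=lambda s: (len(s), tuple(sorted(s))))
    out = {}
    for query in sorted(leaf_names - set(references)):
        label = "unplaced"
        for side in ordered:
            if query not in side:
                continue
            groups = {references[x] for x in side if x in references}
            if not groups:
                continue
            label = groups.pop() if len(groups) == 1 else "unplaced"
            break
        out[query] = label
    return GroupAssignment(out)
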