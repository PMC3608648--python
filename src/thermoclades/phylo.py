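"""Protein-family phylogenetics: Poisson distances, NJ, bootstrap.

Distances between aligned protein sequences are computed as p-distances
under pairwise deletion (gapped columns dropped per pair) and corrected for
multiple hits with the Poisson transform ``d = -ln(1 - p)``.  Trees are
built with Saitou-Nei neighbor joining; ties in the Q criterion break on the
smallest label pair, making the output deterministic and invariant to taxon
input order.  Bootstrap support resamples alignment columns with
replacement and reports, for every internal split of the full-data tree,
the percentage of replicate trees containing it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .profiles import DistanceMatrix

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class ProteinAlignment:
    """Gap-aware protein alignment: equal-length rows over residues + '-'."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("need >= 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows are not equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "ProteinAlignment":
        labels = list(seqs)
        return cls(labels=labels, rows=[seqs[k] for k in labels])

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")


def pairwise_pdistance(row_a: str, row_b: str) -> float:
    """Mismatch fraction over columns where neither row has a gap."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    compared = mismatches = 0
    for a, b in zip(row_a, row_b):
        if a == GAP or b == GAP:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise ValueError("no shared gap-free columns: distance undefined")
    return mismatches / compared


def poisson_correct(p: float) -> float:
    """Poisson-corrected distance ``d = -ln(1 - p)`` in substitutions/site."""
    if not 0 <= p < 1:
        raise ValueError(f"p-distance {p} outside [0, 1): saturated or invalid")
    return -math.log1p(-p)


def alignment_distances(aln: ProteinAlignment) -> DistanceMatrix:
    """Poisson-corrected pairwise distance matrix of an alignment."""
    n = len(aln.labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_correct(
                pairwise_pdistance(aln.rows[i], aln.rows[j])
            )
    return DistanceMatrix(labels=list(aln.labels), values=d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties break on the smallest (label, label) pair, where a
    cluster's label is the smallest leaf name it contains.  Negative branch
    length estimates are clamped to zero with the deficit transferred to the
    sister branch so the joined pair's distance is preserved.  The returned
    tree is unrooted, represented with a trifurcating root.
    """
    labels = dist.labels
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("non-finite distances")

    d = dist.values.astype(float).copy()
    nodes = [Clade(name=lab) for lab in labels]
    keys = list(labels)  # smallest leaf name per active node

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair)
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = Clade(clades=[child_i, child_j])
        new_key = min(keys[i], keys[j])
        du = np.array(
            [(d[i, k] + d[j, k] - d[i, j]) / 2 for k in range(m) if k not in (i, j)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = du
        d[:-1, -1] = du
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new_key]

    # final three-node star: closed-form branch lengths
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    a.branch_length = max(la, 0.0)
    b.branch_length = max(lb, 0.0)
    c.branch_length = max(lc, 0.0)
    order = np.argsort(keys, kind="stable")
    root = Clade(clades=[nodes[k] for k in order])
    return Tree(root=root, rooted=False)


def tree_splits(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the tree's leaf set, each canonicalized as
    the side *not* containing the alphabetically first taxon."""
    taxa = sorted(t.name for t in tree.get_terminals())
    ref = taxa[0]
    full = set(taxa)
    splits = set()
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = {t.name for t in clade.get_terminals()}
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            splits.add(frozenset(side))
    return splits


def total_tree_length(tree: Tree) -> float:
    return sum(c.branch_length or 0.0 for c in tree.find_clades() if c is not tree.root)


def patristic_distances(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (labels sorted)."""
    leaves = sorted(tree.get_terminals(), key=lambda c: c.name)
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.distance(leaves[i], leaves[j])
    return DistanceMatrix(labels=[l.name for l in leaves], values=d)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(aln: ProteinAlignment, n_reps: int, seed: int = 0) -> Tree:
    """NJ tree of the full alignment with per-split bootstrap supports.

    Each replicate resamples columns with replacement, recomputes pairwise-
    deletion p-distances with Poisson correction, and rebuilds the NJ tree;
    support is the percentage of successful replicates containing each
    internal split of the full-data tree.  Replicates in which any pairwise
    distance is undefined (no shared gap-free columns, or p = 1) are skipped
    and counted with a warning.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = nj_tree(alignment_distances(aln))
    target_splits = tree_splits(tree)
    counts = {s: 0 for s in target_splits}
    arr = aln.to_array()
    n_cols = aln.n_columns
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        sampled = arr[:, cols]
        rows = ["".join(r) for r in sampled]
        try:
            rep_dist = alignment_distances(
                ProteinAlignment(labels=list(aln.labels), rows=rows)
            )
            rep_tree = nj_tree(rep_dist)
        except ValueError:
            skipped += 1
            continue
        rep_splits = tree_splits(rep_tree)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    if skipped:
        logger.warning("bootstrap: skipped %d/%d replicates with undefined distances",
                       skipped, n_reps)
    effective = n_reps - skipped
    if effective == 0:
        raise ValueError("all bootstrap replicates had undefined distances")
    taxa = sorted(t.name for t in tree.get_terminals())
    ref = taxa[0]
    full = set(taxa)
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = {t.name for t in clade.get_terminals()}
        if ref in side:
            side = full - side
        key = frozenset(side)
        if key in counts:
            clade.confidence = 100.0 * counts[key] / effective
    return tree


def assign_sequence_clusters(tree: Tree, support_threshold: float) -> dict[str, int]:
    """Group leaves by maximal subtrees whose defining split meets the
    support threshold; leaves under no such subtree become singletons.

    Because NJ places its trifurcation arbitrarily, the walk runs on a
    midpoint-rooted copy (so a long internal branch separates families at
    the root) while supports are looked up by split, which re-rooting
    preserves.  Trivial splits are present in every replicate and count as
    support 100.  Cluster ids are integers ordered by each cluster's
    smallest leaf name.
    """
    if not 0 <= support_threshold <= 100:
        raise ValueError("support threshold must be in [0, 100]")
    taxa = sorted(t.name for t in tree.get_terminals())
    ref, full = taxa[0], set(taxa)

    def canonical(names: set[str]) -> frozenset[str]:
        return frozenset(full - names if ref in names else names)

    support: dict[frozenset[str], float] = {}
    missing = False
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        side = canonical({t.name for t in clade.get_terminals()})
        if 2 <= len(side) <= len(full) - 2:
            if clade.confidence is None:
                missing = True
            else:
                support[side] = float(clade.confidence)
    if missing:
        raise ValueError("tree lacks bootstrap supports on internal splits")

    import copy

    rooted = copy.deepcopy(tree)
    try:
        rooted.root_at_midpoint()
    except Exception:  # zero-length degenerate trees: keep original rooting
        rooted = copy.deepcopy(tree)

    def clade_support(clade: Clade) -> float:
        side = canonical({t.name for t in clade.get_terminals()})
        if len(side) < 2 or len(side) > len(full) - 2:
            return 100.0  # trivial split, contained in every replicate tree
        return support.get(side, 0.0)

    clusters: list[list[str]] = []

    def walk(clade: Clade) -> None:
        if clade.is_terminal():
            clusters.append([clade.name])
            return
        if clade_support(clade) >= support_threshold:
            clusters.append(sorted(t.name for t in clade.get_terminals()))
            return
        for sub in clade.clades:
            walk(sub)

    for sub in rooted.root.clades:
        walk(sub)
    clusters.sort(key=lambda g: g[0])
    return {leaf: i for i, group in enumerate(clusters) for leaf in group}


def write_newick(tree: Tree, path) -> None:
    """Newick export with bootstrap supports as internal-node labels."""
    from Bio import Phylo

    Phylo.write(tree, path, "newick", format_confidence="%g")
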