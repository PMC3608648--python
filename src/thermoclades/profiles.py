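"""Functional-profile construction and hierarchical clade clustering.

Genomes are summarized as count vectors over functional-term identifiers
(COG-like, KO-like or TIGRFAM-like qualifiers); agglomerative clustering of
a profile distance matrix yields a dendrogram whose major subtrees are the
clades.  The default configuration — correlation distance on row-normalized
counts with average linkage — mirrors the classic gene-expression clustering
defaults; metric and linkage are exposed because different choices are
defensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRICS = ("correlation", "euclidean")
NORMALIZATIONS = ("none", "relative")
LINKAGES = ("average", "complete", "single")


def build_profile_matrix(
    assignments: dict[str, pd.DataFrame], qualifier: str = "COG-like"
) -> pd.DataFrame:
    """Genome x term count matrix from per-genome gene->term assignments.

    Each value of ``assignments`` is a two-column frame (gene_id, term_id).
    Counts are genes per term per genome; terms absent from a genome get 0;
    term columns come out lexicographic, genome rows in input order.
    """
    rows = {}
    for genome, table in assignments.items():
        if table.empty:
            rows[genome] = pd.Series(dtype=int)
            continue
        genes = table.iloc[:, 0]
        if genes.duplicated().any():
            dup = genes[genes.duplicated()].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r} in genome {genome}")
        rows[genome] = table.iloc[:, 1].value_counts()
    profile = pd.DataFrame.from_dict(rows, orient="index")
    profile = profile.reindex(index=list(assignments)).fillna(0).astype(int)
    profile = profile.reindex(sorted(profile.columns), axis=1)
    profile.attrs["qualifier"] = qualifier
    return profile


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero-diagonal, nonnegative

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distance entries")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("nonzero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def profile_distance(
    profile: pd.DataFrame, metric: str = "correlation", normalize: str = "relative"
) -> DistanceMatrix:
    """Pairwise profile distances.

    correlation: ``1 - Pearson r`` between (optionally row-normalized)
    profiles, in [0, 2]; euclidean: standard L2.  Row normalization
    ("relative") divides each genome's counts by its total so genome size
    drops out.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if normalize not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalize!r}")
    if len(profile) < 2:
        raise ValueError("need >= 2 genomes")
    x = profile.to_numpy(dtype=float)
    if normalize == "relative":
        totals = x.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        x = x / totals
    if metric == "correlation":
        sds = x.std(axis=1)
        for label, sd in zip(profile.index, sds):
            if sd == 0:
                raise ValueError(f"zero-variance profile for genome {label!r}")
        d = 1.0 - np.corrcoef(x)
    else:
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    d = (d + d.T) / 2.0  # symmetrize away rounding noise
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return DistanceMatrix(labels=list(profile.index), values=d)


@dataclass
class DendrogramNode:
    """Binary merge-tree node; leaves carry genome ids, internal nodes the
    merge height.  ``members`` is the sorted leaf tuple (the deterministic
    sort key used for tie-breaks)."""

    members: tuple[str, ...]
    height: float
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def label(self) -> str:
        return self.members[0]


@dataclass
class Dendrogram:
    root: DendrogramNode
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]  # in merge order

    @property
    def leaves(self) -> list[str]:
        return sorted(self.root.members)


def hierarchical_cluster(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with deterministic smallest-label-pair
    tie-breaks.  Linkage distances are computed from the original matrix
    (unweighted average / complete / single), so the result is invariant to
    genome input order."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    labels = dist.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    active: list[DendrogramNode] = [
        DendrogramNode(members=(lab,), height=0.0) for lab in sorted(labels)
    ]
    merges = []
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                pair_d = [
                    dist.values[idx[p], idx[q]] for p in a.members for q in b.members
                ]
                if linkage == "average":
                    d = float(np.mean(pair_d))
                elif linkage == "complete":
                    d = float(np.max(pair_d))
                else:
                    d = float(np.min(pair_d))
                key = (d, min(a.label, b.label), max(a.label, b.label))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        a, b = active[i], active[j]
        left, right = (a, b) if a.label <= b.label else (b, a)
        node = DendrogramNode(
            members=tuple(sorted(a.members + b.members)),
            height=d,
            left=left,
            right=right,
        )
        merges.append((left.members, right.members, d))
        active = [n for k, n in enumerate(active) if k not in (i, j)] + [node]
    return Dendrogram(root=active[0], merges=merges)


def cut_clades(dend: Dendrogram, k: int) -> dict[str, int]:
    """Cut the ``k - 1`` highest merges, yielding ``k`` clades.

    Labels are integers 0..k-1 ordered by each clade's smallest member id.
    """
    n = len(dend.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    # merges are monotone under the supported linkages: the last k-1 merges
    # are the highest, so undoing them leaves k groups
    kept = dend.merges[: len(dend.merges) - (k - 1)]
    parent = {leaf: leaf for leaf in dend.leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for left, right, _ in kept:
        ra, rb = find(left[0]), find(right[0])
        parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = {}
    for leaf in dend.leaves:
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    return {leaf: c for c, group in enumerate(ordered) for leaf in group}


def dendrogram_to_newick(dend: Dendrogram, precision: int = 6) -> str:
    """Newick export under the half-height convention: a node sits at
    ``merge height / 2`` from the leaves, so branch lengths read like a
    phylogram and leaf-to-leaf path length equals the merge height."""

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def render(node: DendrogramNode, parent_height: float) -> str:
        display = 0.0 if node.is_leaf else node.height / 2.0
        branch = fmt(parent_height - display)
        if node.is_leaf:
            return f"{node.label}:{branch}"
        inner = ",".join(
            render(child, display) for child in (node.left, node.right)
        )
        return f"({inner}):{branch}"

    root = dend.root
    top = root.height / 2.0
    inner = ",".join(render(child, top) for child in (root.left, root.right))
    return f"({inner});"
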