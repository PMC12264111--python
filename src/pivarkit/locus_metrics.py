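"""Splicing diagnostics and genetic-vs-expression distance trees.

Splicing efficiency is the fraction of split reads among reads assigned to
the 14-bp splice-site windows of a junction (7 bp exonic + 7 bp intronic on
each side); relative intron expression is intron coverage over the mean of
the flanking exons.  Strain trees are UPGMA dendrograms on Euclidean
distances, compared by Robinson-Foulds distance and the Adjusted Rand
Index of their k-cut flat clusterings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .genomic_io import GenomicInterval

__all__ = [
    "SpliceSite",
    "SplicingResult",
    "DistanceTree",
    "TreeComparison",
    "splice_sites_for_intron",
    "splicing_efficiency",
    "relative_intron_expression",
    "build_distance_tree",
    "compare_trees",
    "adjusted_rand_index",
]


@dataclass(frozen=True)
class SpliceSite:
    """A 14-bp window straddling one end of an intron."""

    junction_id: str
    side: str  # "donor" | "acceptor"
    window: GenomicInterval

    def __post_init__(self):
        if self.window.length != 14:
            raise ValueError("splice-site window must be exactly 14 bp")
        if self.side not in ("donor", "acceptor"):
            raise ValueError("side must be donor or acceptor")


def splice_sites_for_intron(
    junction_id: str, chrom: str, intron_start: int, intron_end: int, pad: int = 7
) -> tuple[SpliceSite, SpliceSite]:
    """Donor/acceptor windows extending ``pad`` bp into exon and intron."""
    donor = SpliceSite(
        junction_id, "donor",
        GenomicInterval(chrom, intron_start - pad, intron_start + pad, f"{junction_id}_donor"),
    )
    acceptor = SpliceSite(
        junction_id, "acceptor",
        GenomicInterval(chrom, intron_end - pad, intron_end + pad, f"{junction_id}_acceptor"),
    )
    return donor, acceptor


@dataclass
class SplicingResult:
    efficiency: dict[str, float | None]  # junction_id -> efficiency (None if no reads)
    split_counts: dict[str, int]
    unsplit_counts: dict[str, int]


def splicing_efficiency(
    junction_reads: pd.DataFrame,
    splice_sites: list[SpliceSite],
    min_frac: float = 0.5,
) -> SplicingResult:
    """Split-read splicing efficiency per junction.

    ``junction_reads`` columns: chrom, start, end, split (0/1).  A read is
    assigned to a splice-site window when the overlap covers at least
    ``min_frac`` of the window (>= 7 of 14 bp by default); donor and
    acceptor assignments are pooled per junction.  Efficiency is
    split / (split + unsplit), None when no reads are assigned.
    """
    split_counts: dict[str, int] = {}
    unsplit_counts: dict[str, int] = {}
    for site in splice_sites:
        split_counts.setdefault(site.junction_id, 0)
        unsplit_counts.setdefault(site.junction_id, 0)
    chroms = junction_reads["chrom"].to_numpy()
    starts = junction_reads["start"].to_numpy()
    ends = junction_reads["end"].to_numpy()
    splits = junction_reads["split"].to_numpy().astype(bool)
    need = min_frac * 14
    for site in splice_sites:
        w = site.window
        ov = np.minimum(ends, w.end) - np.maximum(starts, w.start)
        assigned = (chroms == w.chrom) & (ov >= need)
        split_counts[site.junction_id] += int((assigned & splits).sum())
        unsplit_counts[site.junction_id] += int((assigned & ~splits).sum())
    efficiency: dict[str, float | None] = {}
    for jid in split_counts:
        total = split_counts[jid] + unsplit_counts[jid]
        efficiency[jid] = split_counts[jid] / total if total else None
    return SplicingResult(efficiency, split_counts, unsplit_counts)


def relative_intron_expression(
    intron_coverage: float, exon_coverage_left: float, exon_coverage_right: float
) -> float:
    """Mean intron coverage over the mean of the two flanking exon coverages."""
    exon_mean = (exon_coverage_left + exon_coverage_right) / 2.0
    if exon_mean <= 0:
        raise ValueError("relative intron expression undefined: zero exon coverage")
    return intron_coverage / exon_mean


# ---------------------------------------------------------------------------
# distance trees


@dataclass
class TreeNode:
    children: list = field(default_factory=list)
    leaf: str | None = None
    height: float = 0.0

    def leaves(self) -> frozenset:
        if self.leaf is not None:
            return frozenset({self.leaf})
        return frozenset().union(*(c.leaves() for c in self.children))

    def newick(self) -> str:
        def rec(node, parent_height):
            blen = parent_height - node.height
            if node.leaf is not None:
                return f"{node.leaf}:{blen:g}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{blen:g}"

        inner = ",".join(rec(c, self.height) for c in self.children)
        return f"({inner});"


@dataclass
class DistanceTree:
    labels: list[str]
    root: TreeNode
    distances: np.ndarray  # condensed-form source matrix (square)
    linkage: np.ndarray
    degenerate: bool = False

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each as its smaller-or-
        lexicographically-first side."""
        all_leaves = frozenset(self.labels)
        splits = set()

        def visit(node):
            if node.leaf is not None:
                return
            side = node.leaves()
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            for c in node.children:
                visit(c)

        visit(self.root)
        return splits

    def cut(self, k: int = 2) -> dict[str, int]:
        """Flat clustering from cutting the dendrogram into k groups."""
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))


def build_distance_tree(
    features: pd.DataFrame, method: str = "upgma", metric: str = "euclidean"
) -> DistanceTree:
    """UPGMA tree from Euclidean distances between the rows of ``features``.

    Rows are strains; columns are features (SNP genotypes or expression
    values).  With ``metric="precomputed"`` the input is taken as a square
    distance matrix instead.  Ties are broken deterministically by sorting
    rows by label first.  Fewer than 3 strains is an error (no informative
    topology).
    """
    if method not in ("upgma", "average"):
        raise ValueError(f"unsupported tree method {method!r}")
    features = features.sort_index()
    if metric == "precomputed":
        features = features[features.index]  # order columns like rows
    labels = [str(x) for x in features.index]
    if len(labels) < 3:
        raise ValueError("need >= 3 strains for a tree")
    if len(set(labels)) != len(labels):
        raise ValueError("strain labels must be unique")
    if metric == "precomputed":
        square = features.to_numpy(dtype=float)
        if not np.allclose(square, square.T) or np.abs(np.diag(square)).max() > 0:
            raise ValueError("precomputed matrix must be symmetric with zero diagonal")
        condensed = squareform(square, checks=False)
    else:
        condensed = pdist(features.to_numpy(dtype=float), metric=metric)
        square = squareform(condensed)
    Z = hierarchy.linkage(condensed, method="average")

    nodes = [TreeNode(leaf=lab) for lab in labels]
    for row in Z:
        left, right, height = int(row[0]), int(row[1]), float(row[2])
        nodes.append(TreeNode(children=[nodes[left], nodes[right]], height=height / 2.0))
    root = nodes[-1]
    return DistanceTree(labels, root, square, Z, degenerate=bool(np.allclose(condensed, 0)))


def adjusted_rand_index(labels_a: dict, labels_b: dict) -> float:
    """Adjusted Rand Index between two flat clusterings of the same items."""
    items = sorted(labels_a)
    if sorted(labels_b) != items:
        raise ValueError("clusterings must cover the same items")
    a = pd.Categorical([labels_a[i] for i in items]).codes
    b = pd.Categorical([labels_b[i] for i in items]).codes
    n = len(items)
    contingency = np.zeros((a.max() + 1, b.max() + 1))
    for i, j in zip(a, b):
        contingency[i, j] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class TreeComparison:
    rf_distance: int
    ari: float


def compare_trees(t1: DistanceTree, t2: DistanceTree, k: int = 2) -> TreeComparison:
    """Robinson-Foulds distance plus ARI of the k-cut flat clusterings."""
    if set(t1.labels) != set(t2.labels):
        raise ValueError("trees must share the same leaf set")
    rf = len(t1.bipartitions() ^ t2.bipartitions())
    ari = adjusted_rand_index(t1.cut(k), t2.cut(k))
    return TreeComparison(rf, ari)
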