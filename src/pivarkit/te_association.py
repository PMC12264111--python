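"""Association of transposable-element variants with cluster expression.

TE variants are grouped into SINE / LINE / ERV / IAP classes (IAPs count
under both IAP and ERV); clusters are TEV-positive for a class when a
variant lies within a proximity window, optionally restricted to variants
in sense or antisense orientation relative to the cluster strand.
Association uses Fisher's exact test on the DE x TEV 2x2 table and the
Wilcoxon rank-sum test on fold-change groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval

__all__ = [
    "TEVariant",
    "AssociationTable",
    "classify_tevs",
    "read_tev_table",
    "annotate_cluster_tev_proximity",
    "fisher_exact_test",
    "wilcoxon_rank_sum",
    "run_te_association",
]

TE_CLASSES = ("SINE", "LINE", "ERV", "IAP")
STRAND_MODES = ("any", "sense", "antisense")


@dataclass(frozen=True)
class TEVariant:
    chrom: str
    start: int
    end: int
    name: str
    strand: str
    raw_annotation: str
    classes: frozenset
    present_in: frozenset

    def __post_init__(self):
        if not self.present_in:
            raise ValueError("TE variant must be present in at least one strain")
        if self.strand not in ("+", "-"):
            raise ValueError("TE variant strand must be + or -")

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.name, self.strand)


def _classes_from_annotation(annotation: str) -> frozenset:
    """SINE if annotated SINE; LINE for LINE/LINE fragments; IAP-I is both
    IAP and ERV; everything else is ERV (the residual class)."""
    if not annotation:
        raise ValueError("empty TE annotation")
    upper = annotation.upper()
    if upper.startswith("SINE") or "SINE" in upper.split("/"):
        return frozenset({"SINE"})
    if "LINE" in upper:
        return frozenset({"LINE"})
    if upper.startswith("IAP-I"):
        return frozenset({"ERV", "IAP"})
    return frozenset({"ERV"})


def classify_tevs(records: list[dict]) -> list[TEVariant]:
    """Build TEVariant objects from raw records.

    Each record needs chrom/start/end/name/strand plus ``raw_annotation``
    and ``present_in`` (iterable of strain labels).
    """
    out = []
    for rec in records:
        out.append(
            TEVariant(
                rec["chrom"], int(rec["start"]), int(rec["end"]),
                str(rec.get("name", ".")), rec["strand"],
                rec["raw_annotation"],
                _classes_from_annotation(rec["raw_annotation"]),
                frozenset(rec["present_in"]),
            )
        )
    return out


def read_tev_table(path) -> list[TEVariant]:
    """TEV TSV dialect: BED6 columns + raw_annotation + comma-separated strains."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = [
        dict(
            chrom=row["chrom"], start=row["start"], end=row["end"], name=row["name"],
            strand=row["strand"], raw_annotation=row["raw_annotation"],
            present_in=str(row["present_in"]).split(","),
        )
        for _, row in df.iterrows()
    ]
    return classify_tevs(records)


def write_tev_table(path, tevs: list[TEVariant]) -> None:
    rows = [
        dict(
            chrom=t.chrom, start=t.start, end=t.end, name=t.name, score=0,
            strand=t.strand, raw_annotation=t.raw_annotation,
            present_in=",".join(sorted(t.present_in)),
        )
        for t in tevs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotate_cluster_tev_proximity(
    clusters: list[GenomicInterval],
    tevs: list[TEVariant],
    window: int = 5_000,
    te_classes: tuple = TE_CLASSES,
    strand_modes: tuple = STRAND_MODES,
    strains: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format boolean table: is each cluster TEV-positive.

    One row per (cluster, te_class, strand_mode, strain); ``positive`` is
    True when some TEV of that class carried by the strain has edge-to-edge
    gap <= ``window`` from the cluster.  Sense mode requires the TEV strand
    to equal the cluster's assigned strand, antisense the opposite;
    bi-directional ("both") clusters are excluded from sense/antisense rows.
    """
    if strains is None:
        strains = sorted({s for t in tevs for s in t.present_in})
    rows = []
    for cl in clusters:
        near = [
            t for t in tevs
            if t.chrom == cl.chrom
            and max(0, max(cl.start, t.start) - min(cl.end, t.end)) <= window
        ]
        for te_class in te_classes:
            of_class = [t for t in near if te_class in t.classes]
            for mode in strand_modes:
                if mode != "any" and cl.strand == "both":
                    continue
                if mode == "sense":
                    cand = [t for t in of_class if t.strand == cl.strand]
                elif mode == "antisense":
                    cand = [t for t in of_class if t.strand != cl.strand]
                else:
                    cand = of_class
                for strain in strains:
                    rows.append(
                        dict(
                            cluster_id=cl.name, te_class=te_class, strand_mode=mode,
                            strain=strain,
                            positive=any(strain in t.present_in for t in cand),
                        )
                    )
    return pd.DataFrame(rows)


def fisher_exact_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p).  The p-value sums hypergeometric probabilities
    of all tables with the same margins whose probability does not exceed
    the observed table's (the minimum-likelihood definition).  Odds ratio is
    (a*d)/(b*c); inf when b*c == 0 and a*d > 0, nan for degenerate margins.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return math.nan, 1.0
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p via DP over doubled midranks."""
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2 * stats.rankdata(pooled)).astype(int)
    n1 = len(x)
    obs = int(ranks2[:n1].sum())
    total = int(ranks2.sum())
    # dp[k][s] = number of k-subsets of ranks2 with sum s
    max_s = total
    dp = np.zeros((n1 + 1, max_s + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(min(n1, 1_000), 0, -1):
            dp[k, r:] += dp[k - 1, : max_s + 1 - r]
    dist = dp[n1]
    n_total = dist.sum()
    mean = total * n1 / len(pooled)
    dev = abs(obs - mean)
    sums = np.arange(max_s + 1)
    p = dist[np.abs(sums - mean) >= dev - 1e-9].sum() / n_total
    return float(min(1.0, p))


def wilcoxon_rank_sum(x, y, two_sided: bool = True, exact_max_n: int = 20) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation distribution of the rank-sum (midranks for ties) when
    the pooled size is <= ``exact_max_n``; otherwise a normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    if not two_sided:
        raise NotImplementedError("only the two-sided test is implemented")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n1, n2 = len(x), len(y)
    if n1 + n2 <= exact_max_n:
        return _rank_sum_exact_p(x, y)
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mean = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n1 + n2) * (n1 + n2 - 1))
    var = n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2 * stats.norm.sf(max(z, 0.0))))


@dataclass
class AssociationTable:
    te_class: str
    strand_mode: str
    a: int  # DE+, TEV+
    b: int  # DE+, TEV-
    c: int  # DE-, TEV+
    d: int  # DE-, TEV-
    odds_ratio: float
    p: float


@dataclass
class FoldChangeGroups:
    te_class: str
    strand_mode: str
    strain_a: str
    strain_b: str
    groups: pd.DataFrame  # cluster_id, log2fc, group
    wilcoxon_p: float | None


def run_te_association(
    clusters: list[GenomicInterval],
    de_summary: pd.DataFrame,
    tevs: list[TEVariant],
    strains: list[str],
    mean_normalized: pd.DataFrame | None = None,
    strain_pair: tuple[str, str] | None = None,
    window: int = 5_000,
    min_comparisons: int = 1,
    te_classes: tuple = TE_CLASSES,
) -> tuple[list[AssociationTable], list[FoldChangeGroups]]:
    """DE x TEV association tables and fold-change group comparisons.

    A cluster counts as differentially expressed when it is significant in
    at least ``min_comparisons`` pairwise comparisons (``de_summary`` from
    :func:`pivarkit.expression_analysis.summarize_de`).  A cluster is
    TEV-positive for a class/mode when any strain carries a qualifying
    variant in proximity.  When ``mean_normalized`` (clusters x strains mean
    normalized counts) and ``strain_pair`` are given, clusters are split by
    TEV carrier status between the two strains and the log2 fold changes of
    the two carrier groups are compared with the Wilcoxon rank-sum test.
    """
    prox = annotate_cluster_tev_proximity(clusters, tevs, window, te_classes,
                                          strains=strains)
    de_pos = set(de_summary.index[de_summary["n_significant"] >= min_comparisons])

    tables: list[AssociationTable] = []
    for te_class in te_classes:
        for mode in STRAND_MODES:
            sub = prox[(prox["te_class"] == te_class) & (prox["strand_mode"] == mode)]
            if sub.empty:
                continue
            pos_by_cluster = sub.groupby("cluster_id")["positive"].any()
            a = b = c = d = 0
            for cid, tev_pos in pos_by_cluster.items():
                de = cid in de_pos
                if de and tev_pos:
                    a += 1
                elif de:
                    b += 1
                elif tev_pos:
                    c += 1
                else:
                    d += 1
            odds, p = fisher_exact_test(a, b, c, d)
            tables.append(AssociationTable(te_class, mode, a, b, c, d, odds, p))

    fc_groups: list[FoldChangeGroups] = []
    if mean_normalized is not None and strain_pair is not None:
        strain_a, strain_b = strain_pair
        with np.errstate(divide="ignore"):
            log2fc = np.log2(
                (mean_normalized[strain_a] + 0.5) / (mean_normalized[strain_b] + 0.5)
            )
        for te_class in te_classes:
            for mode in ("sense", "antisense"):
                sub = prox[(prox["te_class"] == te_class) & (prox["strand_mode"] == mode)]
                if sub.empty:
                    continue
                pos = sub.pivot_table(
                    index="cluster_id", columns="strain", values="positive", aggfunc="any"
                )
                rows = []
                for cid in pos.index:
                    if cid not in log2fc.index:
                        continue
                    in_a = bool(pos.loc[cid].get(strain_a, False))
                    in_b = bool(pos.loc[cid].get(strain_b, False))
                    if in_a and not in_b:
                        group = "tev_only_in_A"
                    elif in_b and not in_a:
                        group = "tev_only_in_B"
                    elif not in_a and not in_b:
                        group = "no_tev"
                    else:
                        continue  # carried by both strains: uninformative
                    rows.append(dict(cluster_id=cid, log2fc=float(log2fc[cid]), group=group))
                gdf = pd.DataFrame(rows)
                ga = gdf[gdf["group"] == "tev_only_in_A"]["log2fc"] if len(gdf) else []
                gb = gdf[gdf["group"] == "tev_only_in_B"]["log2fc"] if len(gdf) else []
                if len(ga) and len(gb):
                    wp = wilcoxon_rank_sum(ga, gb)
                else:
                    wp = None
                fc_groups.append(
                    FoldChangeGroups(te_class, mode, strain_a, strain_b, gdf, wp)
                )
    return tables, fc_groups
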