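"""Cross-strain coordinate conversion, same-strand union merge and filtering.

Strain genomes are related to the common reference by block maps (a
chain-like TSV of colinear alignment blocks).  Clusters that do not convert
one-to-one are excluded; per-strain cluster sets are merged by strand-aware
interval union; the merged set is then filtered on repeat content,
bi-over-mono overlap and minimum counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genomic_io import CountMatrix, GenomicInterval

__all__ = [
    "StrainCoordinateMap",
    "MergedClusterSet",
    "read_strain_map",
    "convert_intervals",
    "merge_same_strand_union",
    "apply_cluster_filters",
]

MAP_COLUMNS = ["source_chrom", "source_start", "source_end", "target_chrom", "target_start"]


@dataclass
class StrainCoordinateMap:
    """Ordered colinear alignment blocks from one strain genome to the reference."""

    strain: str
    blocks: pd.DataFrame  # MAP_COLUMNS

    def __post_init__(self):
        missing = [c for c in MAP_COLUMNS if c not in self.blocks.columns]
        if missing:
            raise ValueError(f"strain map missing columns: {missing}")
        df = self.blocks.sort_values(["source_chrom", "source_start"]).reset_index(drop=True)
        if (df["source_end"] <= df["source_start"]).any():
            raise ValueError("map block with source_end <= source_start")
        # blocks must be non-overlapping in source coordinates
        for _, sub in df.groupby("source_chrom", sort=False):
            s = sub["source_start"].to_numpy()
            e = sub["source_end"].to_numpy()
            if (s[1:] < e[:-1]).any():
                raise ValueError(f"overlapping source blocks in strain map {self.strain!r}")
        self.blocks = df


def read_strain_map(path) -> StrainCoordinateMap:
    df = pd.read_csv(path, sep="\t", dtype={"source_chrom": str, "target_chrom": str})
    if "strain" not in df.columns:
        raise ValueError("strain map TSV needs a 'strain' column")
    strains = df["strain"].unique()
    if len(strains) != 1:
        raise ValueError("one strain map file per strain")
    return StrainCoordinateMap(strains[0], df[MAP_COLUMNS].copy())


def write_strain_map(path, smap: StrainCoordinateMap) -> None:
    out = smap.blocks.copy()
    out["strain"] = smap.strain
    out.to_csv(path, sep="\t", index=False)


def convert_intervals(
    intervals: list[GenomicInterval], smap: StrainCoordinateMap
) -> tuple[list[GenomicInterval], list[tuple[GenomicInterval, str]]]:
    """Lift intervals through a block map; returns (converted, dropped).

    An interval fully inside one block is shifted by that block's offset.
    An interval spanning several blocks converts only when the blocks are
    contiguous in both source and target (the one-to-one case); otherwise it
    is dropped with reason ``not_one_to_one``.  Intervals on chromosomes
    absent from the map are dropped with reason ``no_alignment``.
    Conversion preserves interval length.
    """
    converted: list[GenomicInterval] = []
    dropped: list[tuple[GenomicInterval, str]] = []
    by_chrom = {c: sub for c, sub in smap.blocks.groupby("source_chrom", sort=False)}
    for iv in intervals:
        sub = by_chrom.get(iv.chrom)
        if sub is None:
            dropped.append((iv, "no_alignment"))
            continue
        hit = sub[(sub["source_start"] < iv.end) & (sub["source_end"] > iv.start)]
        if hit.empty:
            dropped.append((iv, "not_one_to_one"))
            continue
        # interval must be fully covered by a source- and target-contiguous run
        rows = hit.sort_values("source_start").to_dict("records")
        if rows[0]["source_start"] > iv.start or rows[-1]["source_end"] < iv.end:
            dropped.append((iv, "not_one_to_one"))
            continue
        ok = True
        for prev, cur in zip(rows, rows[1:]):
            source_contig = cur["source_start"] == prev["source_end"]
            target_contig = (
                cur["target_chrom"] == prev["target_chrom"]
                and cur["target_start"]
                == prev["target_start"] + (prev["source_end"] - prev["source_start"])
            )
            if not (source_contig and target_contig):
                ok = False
                break
        if not ok:
            dropped.append((iv, "not_one_to_one"))
            continue
        offset = rows[0]["target_start"] - rows[0]["source_start"]
        converted.append(
            GenomicInterval(
                rows[0]["target_chrom"], iv.start + offset, iv.end + offset,
                iv.name, iv.strand, iv.extra,
            )
        )
    return converted, dropped


@dataclass
class MergedClusterSet:
    """Non-redundant merged clusters plus provenance and a removal log."""

    clusters: list[GenomicInterval]
    provenance: dict[str, list]  # cluster name -> contributing (strain, name) pairs
    filter_log: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)

    def survivors(self) -> list[GenomicInterval]:
        return list(self.clusters)


def merge_same_strand_union(
    cluster_lists: dict[str, list[GenomicInterval]],
) -> MergedClusterSet:
    """Union-merge overlapping clusters sharing the same strand class.

    Strand classes are ``+``, ``-`` and ``both``; transitively overlapping
    intervals within a class collapse to their union (connected components
    of the overlap graph).  Different classes never merge.
    """
    tagged: list[tuple[GenomicInterval, str]] = []
    for strain, clusters in cluster_lists.items():
        for iv in clusters:
            tagged.append((iv, strain))

    merged: list[GenomicInterval] = []
    provenance: dict[str, list] = {}
    counter = 0
    classes = sorted({iv.strand for iv, _ in tagged})
    for strand in classes:
        members = sorted(
            (t for t in tagged if t[0].strand == strand),
            key=lambda t: (t[0].chrom, t[0].start, t[0].end),
        )
        i = 0
        while i < len(members):
            iv0, strain0 = members[i]
            chrom, start, end = iv0.chrom, iv0.start, iv0.end
            contributors = [(strain0, iv0.name)]
            j = i + 1
            while j < len(members) and members[j][0].chrom == chrom and members[j][0].start < end:
                end = max(end, members[j][0].end)
                contributors.append((members[j][1], members[j][0].name))
                j += 1
            counter += 1
            name = f"merged_{counter}"
            merged.append(GenomicInterval(chrom, start, end, name, strand))
            provenance[name] = contributors
            i = j
    merged.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return MergedClusterSet(merged, provenance)


def apply_cluster_filters(
    merged: MergedClusterSet,
    repeats: list[GenomicInterval],
    tevs: list[GenomicInterval],
    counts: CountMatrix,
    repeat_frac: float = 0.80,
    min_count: int = 10,
) -> MergedClusterSet:
    """Apply the post-merge cluster filters, in order.

    1. remove clusters covered by the union of repeat + TE-variant intervals
       over more than ``repeat_frac`` of their length;
    2. remove bi-directional clusters overlapping a surviving
       mono-directional cluster;
    3. remove clusters whose count is below ``min_count`` in every sample.
    Every removal is recorded in the filter log.
    """
    count_df = counts.to_frame()
    masking = list(repeats) + list(tevs)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in masking:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    def union_cover(iv: GenomicInterval) -> int:
        segs = [
            (max(s, iv.start), min(e, iv.end))
            for s, e in by_chrom.get(iv.chrom, ())
            if s < iv.end and e > iv.start
        ]
        segs.sort()
        covered = 0
        cur_s = cur_e = None
        for s, e in segs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        return covered

    log = list(merged.filter_log)
    stage1 = []
    for iv in merged.clusters:
        if union_cover(iv) > repeat_frac * iv.length:
            log.append((iv.name, "repeat_overlap"))
        else:
            stage1.append(iv)

    monos = [iv for iv in stage1 if iv.strand in ("+", "-")]
    stage2 = []
    for iv in stage1:
        if iv.strand == "both" and any(iv.overlap(m) > 0 for m in monos):
            log.append((iv.name, "bi_over_mono"))
        else:
            stage2.append(iv)

    survivors = []
    for iv in stage2:
        if iv.name in count_df.index and count_df.loc[iv.name].max() < min_count:
            log.append((iv.name, "low_count"))
        else:
            survivors.append(iv)

    provenance = {iv.name: merged.provenance.get(iv.name, []) for iv in survivors}
    return MergedClusterSet(survivors, provenance, log)
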