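"""End-to-end orchestration: call -> merge -> count -> DE -> TE association."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cluster_discovery as cd
from . import cross_strain as xs
from . import expression_analysis as ea
from . import genomic_io as gio
from . import te_association as ta
from .synthetic_data import InbredExperiment, SimulationConfig


@dataclass
class TEAssociationOutcome:
    clusters: list
    counts: gio.CountMatrix
    de_summary: pd.DataFrame
    tables: list  # AssociationTable
    fc_groups: list  # FoldChangeGroups

    def fisher_p(self, te_class: str, mode: str) -> float:
        for t in self.tables:
            if t.te_class == te_class and t.strand_mode == mode:
                return t.p
        return float("nan")

    def fold_changes(self, te_class: str, mode: str):
        for g in self.fc_groups:
            if g.te_class == te_class and g.strand_mode == mode:
                return g
        return None


def inbred_te_pipeline(
    exp: InbredExperiment,
    config: SimulationConfig,
    strain_pair: tuple[str, str] | None = None,
    window: int = 5_000,
) -> TEAssociationOutcome:
    """Run the full analysis on a simulated inbred experiment.

    Calls clusters per sample from the read-level alignments, union-merges
    them across strains by strand class, applies the cluster filters,
    re-counts unique reads, runs pairwise DE between the first two strains
    (or ``strain_pair``) and tests TE-variant association.
    """
    if strain_pair is None:
        strain_pair = (config.strains[0], config.strains[1])
    strain_a, strain_b = strain_pair

    per_strain: dict[str, list[gio.GenomicInterval]] = {}
    for sid, sub in exp.alignments.groupby("sample_id", sort=True):
        reall = cd.reallocate_multimappers(sub)
        called = cd.call_clusters(reall, chrom_sizes=config.genome, sample_id=sid)
        strain = exp.samples.frame.set_index("sample_id").loc[sid, "strain"]
        per_strain.setdefault(strain, []).extend(
            gio.GenomicInterval(c.chrom, c.start, c.end, c.name, c.assigned_strand)
            for c in called
        )

    merged = xs.merge_same_strand_union(per_strain)
    counts0 = gio.count_reads_in_clusters(exp.alignments, merged.clusters)
    final = xs.apply_cluster_filters(
        merged, [], [t.interval() for t in exp.tevs], counts0
    )
    counts = gio.count_reads_in_clusters(exp.alignments, final.clusters)

    de = ea.pairwise_de(counts, exp.samples, strain_a, strain_b)
    summary = ea.summarize_de([de])

    factors = ea.size_factors(counts)
    norm = counts.to_frame() / pd.Series(factors.factors)
    meta = exp.samples.frame.set_index("sample_id")
    means = pd.DataFrame(
        {
            strain: norm[[s for s in counts.sample_ids if meta.loc[s, "strain"] == strain]].mean(axis=1)
            for strain in (strain_a, strain_b)
        }
    )
    tables, fc_groups = ta.run_te_association(
        final.clusters, summary, exp.tevs, [strain_a, strain_b],
        mean_normalized=means, strain_pair=strain_pair, window=window,
    )
    return TEAssociationOutcome(final.clusters, counts, summary, tables, fc_groups)
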