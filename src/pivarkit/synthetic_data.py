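"""Synthetic inputs with the statistical structure the analysis assumes.

Generates negative-binomial cluster counts with strain and TE-variant
effects, read-level alignments consistent with those counts, multi-
generation pedigrees with additive genetic effects at a configurable
heritability, strain coordinate maps with planted non-one-to-one regions,
and split/unsplit junction reads — each with a ground-truth table.

All randomness flows through one seed; identical configs give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genomic_io import CountMatrix, GenomicInterval, SampleTable
from .heritability import Pedigree, build_relationship_matrix
from .locus_metrics import splice_sites_for_intron
from .te_association import TEVariant, classify_tevs

__all__ = [
    "SimulationConfig",
    "simulate_count_matrix",
    "simulate_inbred_experiment",
    "simulate_outbred_pedigree_experiment",
    "simulate_strain_maps",
    "simulate_junction_reads",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_strains: int = 2
    strains: list = field(default_factory=lambda: ["BL6", "CAST"])
    n_clusters: int = 40
    n_samples_per_strain: int = 4
    genome: dict = field(default_factory=lambda: {"chr1": 600_000, "chr2": 600_000})
    nb_dispersion: float = 0.05
    base_mean_counts: float = 300.0
    strain_effect_log2fc: float = 2.0
    fraction_de_clusters: float = 0.0
    tev_effect_log2fc: float = 2.0
    fraction_clusters_with_tev: float = 0.0
    sense_fraction_of_tevs: float = 0.5
    antisense_read_fraction: float = 0.02
    multimapper_fraction: float = 0.0
    background_reads_per_sample: int = 500
    cluster_span: int = 2_000
    tile: int = 1_000
    read_length_range: tuple = (26, 32)
    # pedigree design
    n_pedigrees: int = 7
    generations: int = 5
    litter_size: int = 3
    n_recorded_males: int = 40
    true_h2: float = 0.5
    # junctions
    n_junctions: int = 20
    true_efficiency: float = 0.8
    reads_per_junction: int = 200

    def __post_init__(self):
        if len(self.strains) != self.n_strains:
            self.strains = [f"S{i+1}" for i in range(self.n_strains)]
        for name, frac in (
            ("fraction_de_clusters", self.fraction_de_clusters),
            ("fraction_clusters_with_tev", self.fraction_clusters_with_tev),
            ("sense_fraction_of_tevs", self.sense_fraction_of_tevs),
            ("antisense_read_fraction", self.antisense_read_fraction),
            ("multimapper_fraction", self.multimapper_fraction),
            ("true_h2", self.true_h2),
            ("true_efficiency", self.true_efficiency),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")


def _nb_draw(rng: np.random.Generator, mean, alpha: float):
    """NB with Var = mu + alpha mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def simulate_count_matrix(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, SampleTable, pd.DataFrame]:
    """NB cluster counts with planted strain fixed effects.

    Returns (counts, samples, truth) where truth has one row per cluster
    with its true DE status, effect strain and log2 fold change.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_de = int(round(config.fraction_de_clusters * config.n_clusters))
    if n_de > config.n_clusters:
        raise ValueError("more DE clusters than clusters")
    cluster_ids = [f"cl{i+1}" for i in range(config.n_clusters)]
    de_idx = rng.choice(config.n_clusters, size=n_de, replace=False)
    de_strain = rng.choice(config.strains[1:], size=n_de) if n_de else np.array([])

    sample_rows = []
    for strain in config.strains:
        for r in range(config.n_samples_per_strain):
            sample_rows.append(
                dict(sample_id=f"{strain}_s{r+1}", strain=strain, tissue="testis",
                     batch="b1", individual_id=pd.NA)
            )
    samples = SampleTable(pd.DataFrame(sample_rows))

    base = config.base_mean_counts * np.exp(rng.normal(0, 0.2, size=config.n_clusters))
    truth_lfc = np.zeros(config.n_clusters)
    truth_strain = np.array([""] * config.n_clusters, dtype=object)
    truth_lfc[de_idx] = config.strain_effect_log2fc
    truth_strain[de_idx] = de_strain

    counts = np.zeros((config.n_clusters, len(sample_rows)), dtype=np.int64)
    for j, row in enumerate(sample_rows):
        mean = base.copy()
        boost = truth_strain == row["strain"]
        mean[boost] *= 2.0 ** truth_lfc[boost]
        counts[:, j] = _nb_draw(rng, mean, config.nb_dispersion)
    cm = CountMatrix(cluster_ids, [r["sample_id"] for r in sample_rows], counts)
    truth = pd.DataFrame(
        dict(cluster_id=cluster_ids, base_mean=base, true_de=truth_lfc != 0,
             de_strain=truth_strain, true_log2fc=truth_lfc)
    ).set_index("cluster_id")
    return cm, samples, truth


@dataclass
class InbredExperiment:
    clusters: list  # planted GenomicInterval, tile-aligned
    tevs: list  # TEVariant
    alignments: pd.DataFrame  # all samples pooled, genomic_io dialect + sample_id
    counts: CountMatrix
    samples: SampleTable
    truth: pd.DataFrame  # per-cluster ground truth


def _plant_clusters(config: SimulationConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    """Tile-aligned planted clusters, spaced >= 20 kb apart."""
    chroms = sorted(config.genome)
    spacing = 20_000
    slots = []
    for chrom in chroms:
        size = config.genome[chrom]
        pos = 4 * config.tile  # leave room for upstream TE variants
        while pos + config.cluster_span + 2 * config.tile < size:
            slots.append((chrom, pos))
            pos += config.cluster_span + spacing
    if len(slots) < config.n_clusters:
        raise ValueError(
            f"genome too small: {len(slots)} slots for {config.n_clusters} clusters"
        )
    chosen = sorted(rng.choice(len(slots), size=config.n_clusters, replace=False))
    strands = rng.choice(["+", "-"], size=config.n_clusters)
    return [
        GenomicInterval(slots[s][0], slots[s][1], slots[s][1] + config.cluster_span,
                        f"cl{i+1}", strands[i])
        for i, s in enumerate(chosen)
    ]


def simulate_inbred_experiment(config: SimulationConfig) -> InbredExperiment:
    """Full read-level inbred-strain experiment with planted TEV effects.

    Cluster counts are negative binomial; clusters tagged with a
    sense-strand TE variant get ``tev_effect_log2fc`` added to the log2 mean
    in carrier strains (antisense variants add nothing).  Unique reads are
    placed inside clusters so that counting them reproduces the count
    matrix exactly; multimappers and background reads are extra mass that
    the unique-read counter ignores.
    """
    rng = np.random.default_rng(config.seed)
    clusters = _plant_clusters(config, rng)
    n = config.n_clusters

    # plant TE variants near clusters: sense and antisense sets are drawn
    # independently so antisense carriage is independent of expression status
    n_tev = int(round(config.fraction_clusters_with_tev * n))
    n_sense = int(round(n_tev * config.sense_fraction_of_tevs))
    n_anti = n_tev - n_sense
    sense_idx = rng.choice(n, size=n_sense, replace=False)
    anti_idx = rng.choice(n, size=n_anti, replace=False)
    tev_records = []
    sense_carrier: dict[str, str] = {}
    anti_carrier: dict[str, str] = {}
    k = 0
    for ci in sorted(sense_idx):
        cl = clusters[ci]
        carrier = config.strains[int(rng.integers(len(config.strains)))]
        gap = int(rng.integers(200, 3_000))
        k += 1
        tev_records.append(
            dict(chrom=cl.chrom, start=cl.end + gap, end=cl.end + gap + 400,
                 name=f"tev{k}", strand=cl.strand,
                 raw_annotation="MERVK" if rng.random() < 0.5 else "IAP-I",
                 present_in=[carrier])
        )
        sense_carrier[cl.name] = carrier
    for ci in sorted(anti_idx):
        cl = clusters[ci]
        carrier = config.strains[int(rng.integers(len(config.strains)))]
        gap = int(rng.integers(200, 3_000))
        start = cl.start - gap - 400  # upstream, clear of any sense TEV
        k += 1
        tev_records.append(
            dict(chrom=cl.chrom, start=start, end=start + 400,
                 name=f"tev{k}", strand="-" if cl.strand == "+" else "+",
                 raw_annotation="MERVK" if rng.random() < 0.5 else "IAP-I",
                 present_in=[carrier])
        )
        anti_carrier[cl.name] = carrier
    tevs = classify_tevs(tev_records)

    # extra strain DE effects go on clusters without a sense TEV
    free = [i for i in range(n) if i not in set(sense_idx)]
    n_de = int(round(config.fraction_de_clusters * n))
    if n_de > len(free):
        raise ValueError("more DE clusters requested than TEV-free clusters")
    de_idx = rng.choice(free, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    de_strain = {clusters[i].name: config.strains[int(rng.integers(1, len(config.strains)))]
                 for i in de_idx}

    sample_rows = []
    for strain in config.strains:
        for r in range(config.n_samples_per_strain):
            sample_rows.append(
                dict(sample_id=f"{strain}_s{r+1}", strain=strain, tissue="spermatogonia",
                     batch="b1", individual_id=pd.NA)
            )
    samples = SampleTable(pd.DataFrame(sample_rows))
    sample_ids = [r["sample_id"] for r in sample_rows]

    base = config.base_mean_counts * np.exp(rng.normal(0, 0.2, size=n))
    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    for j, row in enumerate(sample_rows):
        mean = base.copy()
        for i, cl in enumerate(clusters):
            if cl.name in de_strain and de_strain[cl.name] == row["strain"]:
                mean[i] *= 2.0 ** config.strain_effect_log2fc
            if sense_carrier.get(cl.name) == row["strain"]:
                mean[i] *= 2.0 ** config.tev_effect_log2fc
        counts[:, j] = _nb_draw(rng, mean, config.nb_dispersion)
    cm = CountMatrix([c.name for c in clusters], sample_ids, counts)

    # read-level alignments: unique reads inside clusters reproduce counts
    lmin, lmax = config.read_length_range
    aln_frames = []
    read_no = 0
    cluster_zones = {}
    for cl in clusters:
        cluster_zones.setdefault(cl.chrom, []).append((cl.start - lmax, cl.end + lmax))
    chroms = sorted(config.genome)
    chrom_sizes = np.array([config.genome[c] for c in chroms], dtype=float)
    chrom_p = chrom_sizes / chrom_sizes.sum()
    for j, sid in enumerate(sample_ids):
        recs = []
        for i, cl in enumerate(clusters):
            c = int(counts[i, j])
            if c == 0:
                continue
            lens = rng.integers(lmin, lmax + 1, size=c)
            starts = cl.start + rng.integers(0, config.cluster_span - lmax, size=c)
            anti = rng.random(c) < config.antisense_read_fraction
            anti_strand = "-" if cl.strand == "+" else "+"
            for t in range(c):
                read_no += 1
                recs.append(
                    (f"r{read_no}", sid, cl.chrom, int(starts[t]),
                     int(starts[t] + lens[t]), anti_strand if anti[t] else cl.strand, 1)
                )
            n_mm = rng.binomial(c, config.multimapper_fraction)
            for _ in range(n_mm):
                read_no += 1
                rid = f"m{read_no}"
                s1 = cl.start + int(rng.integers(0, config.cluster_span - lmax))
                length = int(rng.integers(lmin, lmax + 1))
                recs.append((rid, sid, cl.chrom, s1, s1 + length, cl.strand, 2))
                bc, bs = _background_pos(rng, chroms, chrom_p, config, cluster_zones, lmax)
                recs.append((rid, sid, bc, bs, bs + length, cl.strand, 2))
        for _ in range(config.background_reads_per_sample):
            read_no += 1
            length = int(rng.integers(lmin, lmax + 1))
            bc, bs = _background_pos(rng, chroms, chrom_p, config, cluster_zones, lmax)
            recs.append((f"b{read_no}", sid, bc, bs, bs + length,
                         "+" if rng.random() < 0.5 else "-", 1))
        aln_frames.append(pd.DataFrame(
            recs, columns=["read_id", "sample_id", "chrom", "start", "end", "strand", "n_hits"]
        ))
    alignments = pd.concat(aln_frames, ignore_index=True)

    truth = pd.DataFrame(
        [
            dict(
                cluster_id=cl.name, chrom=cl.chrom, start=cl.start, end=cl.end,
                strand=cl.strand, base_mean=base[i],
                true_de=cl.name in de_strain, de_strain=de_strain.get(cl.name, ""),
                has_sense_tev=cl.name in sense_carrier,
                sense_tev_carrier=sense_carrier.get(cl.name, ""),
                has_antisense_tev=cl.name in anti_carrier,
                antisense_tev_carrier=anti_carrier.get(cl.name, ""),
                true_effect_log2fc=(
                    config.tev_effect_log2fc
                    if cl.name in sense_carrier
                    else (config.strain_effect_log2fc if cl.name in de_strain else 0.0)
                ),
            )
            for i, cl in enumerate(clusters)
        ]
    ).set_index("cluster_id")
    return InbredExperiment(clusters, tevs, alignments, cm, samples, truth)


def _background_pos(rng, chroms, chrom_p, config, cluster_zones, lmax):
    """Uniform genomic position avoiding planted clusters (+- read length)."""
    for _ in range(1_000):
        ci = int(rng.choice(len(chroms), p=chrom_p))
        chrom = chroms[ci]
        pos = int(rng.integers(0, config.genome[chrom] - lmax))
        if all(not (zs <= pos < ze) for zs, ze in cluster_zones.get(chrom, ())):
            return chrom, pos
    raise RuntimeError("could not place background read outside clusters")


# ---------------------------------------------------------------------------
# outbred pedigree experiment


@dataclass
class OutbredExperiment:
    pedigree: Pedigree
    expression: pd.DataFrame  # clusters x recorded individuals
    covariates: pd.DataFrame  # pedigree_set per recorded individual
    strata: dict  # individual -> (generation, pedigree_set)
    breeding_values: pd.DataFrame  # clusters x recorded individuals (truth)
    true_h2: float


def _build_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation sib-mating lines in two pedigree sets.

    Each pedigree is one breeding line: a founder couple, then
    ``generations`` litters of ``litter_size`` where each generation's
    parents are a brother-sister pair from the previous litter.  Offspring
    at even litter indices are male (index 0 is the next sire, index 1 the
    next dam).  The accumulating inbreeding makes the additive relationship
    matrix highly informative for variance-component estimation.
    """
    rows = []
    for p in range(config.n_pedigrees):
        ped_set = "setA" if p < (config.n_pedigrees + 1) // 2 else "setB"
        sire, dam = f"p{p}f0", f"p{p}f1"
        rows.append(dict(individual_id=sire, sire_id=None, dam_id=None,
                         generation=0, pedigree_set=ped_set))
        rows.append(dict(individual_id=dam, sire_id=None, dam_id=None,
                         generation=0, pedigree_set=ped_set))
        for g in range(1, config.generations + 1):
            litter = []
            for k in range(config.litter_size):
                ind = f"p{p}g{g}o{k}"
                rows.append(dict(individual_id=ind, sire_id=sire, dam_id=dam,
                                 generation=g, pedigree_set=ped_set))
                litter.append(ind)
            sire, dam = litter[0], litter[1]
    return Pedigree(pd.DataFrame(rows))


def _male_candidates(ped: Pedigree, last_k_generations: int = 3) -> list:
    """Recorded-male candidates: even litter indices in the last generations."""
    df = ped.frame
    max_gen = int(df["generation"].max())
    gens = set(range(max_gen - last_k_generations + 1, max_gen + 1))
    return [
        row["individual_id"]
        for _, row in df.iterrows()
        if row["generation"] in gens and int(row["individual_id"].split("o")[-1]) % 2 == 0
    ]


def simulate_outbred_pedigree_experiment(
    config: SimulationConfig, n_clusters: int | None = None
) -> OutbredExperiment:
    """Pedigree + expression with additive genetic effects at ``true_h2``.

    Per cluster, y = pedigree-set effect + u + e with
    u ~ MVN(0, h2 * A) and e ~ N(0, 1 - h2); only designated males of the
    last two generations are recorded.
    """
    if not 0.0 <= config.true_h2 <= 1.0:
        raise ValueError("true_h2 must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    if n_clusters is None:
        n_clusters = config.n_clusters
    ped = _build_pedigree(config)
    rel = build_relationship_matrix(ped)
    df = ped.frame

    candidates = _male_candidates(ped)
    n_rec = min(config.n_recorded_males, len(candidates))
    recorded = sorted(rng.choice(candidates, size=n_rec, replace=False))

    A_sub = rel.submatrix(recorded).A
    vals, vecs = np.linalg.eigh(A_sub)
    factor = vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))

    set_of = dict(zip(df["individual_id"], df["pedigree_set"]))
    gen_of = dict(zip(df["individual_id"], df["generation"]))
    set_effect = {"setA": 0.0, "setB": 0.7}
    offsets = np.array([set_effect[set_of[i]] for i in recorded])

    sigma_a = np.sqrt(config.true_h2)
    sigma_e = np.sqrt(1.0 - config.true_h2)
    U = factor @ rng.normal(size=(len(recorded), n_clusters)) * sigma_a
    E = rng.normal(size=(len(recorded), n_clusters)) * sigma_e
    Y = offsets[:, None] + U + E

    cluster_ids = [f"cl{i+1}" for i in range(n_clusters)]
    expression = pd.DataFrame(Y.T, index=cluster_ids, columns=recorded)
    bv = pd.DataFrame(U.T, index=cluster_ids, columns=recorded)
    covariates = pd.DataFrame({"pedigree_set": [set_of[i] for i in recorded]},
                              index=recorded)
    strata = {i: (gen_of[i], set_of[i]) for i in recorded}
    return OutbredExperiment(ped, expression, covariates, strata, bv, config.true_h2)


# ---------------------------------------------------------------------------
# strain coordinate maps


def simulate_strain_maps(
    genome: dict[str, int],
    strain: str,
    seed: int = 0,
    n_breaks_per_chrom: int = 4,
    gap_prob: float = 0.25,
) -> tuple["pd.DataFrame", list[tuple[str, int, int]]]:
    """Block map with planted non-one-to-one boundaries.

    Splits each chromosome at random break positions into blocks; each kept
    block gets its own target offset (so intervals spanning a break are not
    one-to-one); dropped blocks are unaligned gaps.  Returns the block
    table (strain-map TSV dialect) and the list of kept source blocks.
    An interval converts one-to-one iff it lies fully inside one kept block.
    """
    rng = np.random.default_rng(seed)
    rows = []
    kept_blocks = []
    target_cursor = 0
    for chrom in sorted(genome):
        size = genome[chrom]
        breaks = np.sort(rng.choice(np.arange(10_000, size - 10_000, 1_000),
                                    size=n_breaks_per_chrom, replace=False))
        edges = [0, *[int(b) for b in breaks], size]
        for s, e in zip(edges[:-1], edges[1:]):
            if rng.random() < gap_prob:
                continue  # unaligned gap
            target_cursor += int(rng.integers(1_000, 5_000))  # breaks contiguity
            rows.append(dict(source_chrom=chrom, source_start=s, source_end=e,
                             target_chrom=f"ref_{chrom}", target_start=target_cursor))
            kept_blocks.append((chrom, s, e))
            target_cursor += e - s
    table = pd.DataFrame(rows)
    table["strain"] = strain
    return table, kept_blocks


# ---------------------------------------------------------------------------
# junction reads


def simulate_junction_reads(
    config: SimulationConfig,
    chrom: str = "chr1",
    read_length: int = 30,
    include_negative_controls: bool = False,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Split/unsplit reads over planted splice junctions.

    Each junction gets >= ``reads_per_junction`` reads placed to overlap at
    least 7 bp of its donor or acceptor window; a read is split with
    probability ``true_efficiency``.  Optional negative controls overlap a
    window by exactly 6 bp and must not change the measured efficiency.
    Returns (splice_sites, reads, truth).
    """
    rng = np.random.default_rng(config.seed)
    sites = []
    reads = []
    truth_rows = []
    read_no = 0
    for j in range(config.n_junctions):
        jid = f"jx{j+1}"
        intron_start = 10_000 + j * 5_000
        intron_end = intron_start + 1_500
        donor, acceptor = splice_sites_for_intron(jid, chrom, intron_start, intron_end)
        sites.extend([donor, acceptor])
        eff = config.true_efficiency
        for _ in range(config.reads_per_junction):
            read_no += 1
            w = donor.window if rng.random() < 0.5 else acceptor.window
            start = int(w.start + rng.integers(-(read_length - 14), 1))
            reads.append(dict(read_id=f"j{read_no}", sample_id="s1", chrom=chrom,
                              start=start, end=start + read_length,
                              split=int(rng.random() < eff)))
        if include_negative_controls:
            for _ in range(50):
                read_no += 1
                start = donor.window.end - 6
                reads.append(dict(read_id=f"n{read_no}", sample_id="s1", chrom=chrom,
                                  start=start, end=start + read_length, split=1))
        truth_rows.append(dict(junction_id=jid, true_efficiency=eff,
                               intron_start=intron_start, intron_end=intron_end))
    return sites, pd.DataFrame(reads), pd.DataFrame(truth_rows).set_index("junction_id")
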