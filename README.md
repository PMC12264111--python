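# pivarkit

Strain-level variation analysis of piRNA-cluster expression from small-RNA
sequencing: de novo cluster discovery, cross-strain merging, differential
expression, pedigree-based heritability with permutation nulls, strand-aware
transposable-element association, and splicing diagnostics — plus a
synthetic-data generator so the whole pipeline is testable without any
external downloads.

## Modules

| module | what it does |
| --- | --- |
| `pivarkit.genomic_io` | BED/TSV/FASTQ readers and writers, read length/quality filters, interval overlap, unique-read counting over clusters (min 18 bp overlap) |
| `pivarkit.cluster_discovery` | multimapper reallocation by Gaussian-weighted local unique-read density (±10 kb flank, 1 kb windows), density-threshold cluster calling, mono/bi directionality at the 10% antisense rule |
| `pivarkit.cross_strain` | block-map coordinate conversion with one-to-one semantics, same-strand union merging, post-merge filters (>80% repeat coverage, bi-over-mono, max count < 10) |
| `pivarkit.expression_analysis` | median-of-ratios size factors, log2 transform, moderated NB Wald pairwise DE (\|log2FC\| > 1 & BH FDR 0.05), per-cluster strain ANOVA, global mixed model |
| `pivarkit.heritability` | tabular-method additive relationship matrix, spectral REML heritability, stratified (generation × pedigree set) permutation null with add-one empirical p-values |
| `pivarkit.te_association` | SINE/LINE/ERV/IAP classification, 5 kb proximity with sense/antisense modes, Fisher exact tests, Wilcoxon rank-sum on fold-change groups |
| `pivarkit.locus_metrics` | split-read splicing efficiency at ±7 bp splice-site windows, relative intron expression, UPGMA distance trees, Robinson–Foulds + Adjusted Rand Index comparison |
| `pivarkit.synthetic_data` | seeded generators for all inputs (NB counts with strain/TEV effects, read-level alignments consistent with counts, sib-mating pedigrees with configurable h², coordinate maps, junction reads) with ground-truth tables |
| `pivarkit.workflows` | end-to-end orchestration (call → merge → count → DE → TE association) |

## CLI

```bash
pivarkit simulate --seed 1 --out sim/            # synthetic experiment + truth
pivarkit filter-reads in.fq out.fq               # 19–36 nt, q30 over ≥90%
pivarkit call-clusters sim/alignments.tsv called.bed
pivarkit count sim/alignments.tsv sim/clusters.bed counts.tsv --min-overlap 18
pivarkit merge --clusters BL6=bl6.bed --clusters CAST=cast.bed \
    --repeats repeats.bed --tevs tevs.tsv --counts counts.tsv
pivarkit de --counts counts.tsv --samples samples.tsv --pair BL6,CAST --out de.tsv
pivarkit variance --counts counts.tsv --samples samples.tsv --out var.tsv
pivarkit heritability --pedigree ped.tsv --expression expr.tsv --n-perm 100 --seed 17
pivarkit te-assoc --clusters merged.bed --tevs tevs.tsv --de-summary summary.tsv --out assoc.tsv
pivarkit splice --reads junction_reads.tsv --introns introns.tsv --out eff.tsv
pivarkit trees --genetic snps.tsv --expression expr.tsv --out cmp.json
```

## File dialects

All formats are plain text: BED6 for intervals; alignments as TSV
(`read_id, sample_id, chrom, start, end, strand, n_hits`); count matrices
and sample tables as TSV; pedigrees as TSV (`individual_id, sire_id,
dam_id, generation, pedigree_set`, `0`/empty = founder); strain coordinate
maps as block TSV (`source_chrom, source_start, source_end, target_chrom,
target_start, strain`); TE variants as BED6 + `raw_annotation` +
comma-separated `present_in` strains. Coordinates are 0-based half-open
throughout.
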