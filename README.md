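# cggcat

Catalogue and characterize CGG-class short tandem repeats (STRs): detect
repeat loci in a genome, ingest STR-genotyper VCFs, compute population
polymorphism statistics, compare two genotypers' call sets, annotate loci
with gene-region labels, and test gene panels for enrichment — together with
a synthetic-data generator so the whole pipeline runs and is testable
without any external downloads.

## Modules

| Module | Purpose |
| --- | --- |
| `cggcat.repeat_catalog` | Motif-class repeat detector: exact frame k-mer seeding, wraparound-DP scoring, local-alignment refinement, score/purity/unit filters. |
| `cggcat.genotype_io` | Read REPCN-style genotype VCFs (ExpansionHunter `a/b` and GangSTR `a,b` dialects), call tables, read-evidence locus exclusion, allele call rate. |
| `cggcat.population_stats` | Per-locus medians (lower median), polymorphic flags and rates, per-sample summaries, deviation tables, fraction-polymorphic-by-median. |
| `cggcat.concordance` | Category taxonomy for allele pairs from two genotypers (identical / off-by-one / larger / no-call) and the consistency metric. |
| `cggcat.annotate` | Gene-region labels with fixed precedence and strand-aware 1-kb flanks, per-gene association counts, 2×2 chi-squared panel enrichment, HI/pLI score flags. |
| `cggcat.synth_data` | Synthetic genomes with planted repeats, diploid cohort simulation with length-dependent instability, VCF emission with read-length censoring, toy gene models. |
| `cggcat.pipeline` | One-config orchestration of all stages with manifest + deterministic summary report. |

## CLI

All stages are exposed under one entry point:

```sh
# simulate a genome + cohort
cggcat simulate --config sim.json --out-dir sim/

# detect repeat loci
cggcat catalog --fasta sim/genome.fa --out-bed catalog.bed --out-catalog catalog.json

# ingest genotype VCF, population statistics
cggcat ingest --vcf sim/cohort.vcf --out-table calls.tsv
cggcat popstats --calls calls.tsv --out-prefix pop

# compare two genotypers
cggcat concord --a eh.vcf --b gangstr.vcf --out-prefix conc

# gene-region annotation + panel enrichment
cggcat annotate --loci catalog.bed --genes genes.gff3 \
    --panel panel.txt --universe universe.txt --out-prefix ann

# or everything from one config (TOML or JSON)
cggcat run --config run.toml
```

A minimal `run.toml`:

```toml
out_dir = "results/run1"
fasta = "sim/genome.fa"
vcf = "sim/cohort.vcf"
gff3 = "sim/genes.gff3"
panel = "sim/panel.txt"
universe = "sim/universe.txt"

[detection]
min_units = 4
```

## Conventions

- Coordinates are 0-based half-open internally and in BED output; the
  variant-catalog JSON uses 1-based inclusive regions; locus ids are
  `<chrom>_<1-based start>`.
- Detection defaults: match +2, mismatch −5, indel −17, MinScore 24,
  MinUnits 4, MaxLength 1000, purity PM ≥ 80% / PI ≤ 10% — so a pure
  4-unit repeat scores exactly the retention threshold.
- The simulator's allele model (linear instability in repeat units,
  geometric step sizes, censoring of lengths in (cap, 3·cap)) is an
  explicit stand-in chosen for testability, not a biological claim.
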