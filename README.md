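# gsize

A genome-size estimation toolkit built around the question of why
sequence-based genome size estimates can fall far short of cytometric
measurements in repeat-rich genomes.

It provides:

* **`gsize.simgenome`** — synthetic genomes with controlled repeat structure
  (dispersed families with divergence, tandem arrays, optional heteromorphic
  sex-chromosome pair), uniform substitution-error read simulation with true
  placements retained, and collapsed-repeat "assemblies" that reproduce the
  repeat-collapse mechanism.
* **`gsize.kmer_estimator`** — canonical k-mer counting (2-bit packed for
  k ≤ 31), multiplicity histograms in the `jellyfish histo` TSV dialect,
  modal k-mer coverage with an automatic error cutoff, and the
  total-k-mers / modal-coverage size estimator, including a k = 21…31 sweep.
* **`gsize.coverage_estimator`** — per-base depth histograms, modal depth,
  sum-of-coverage extrapolation (Σdepth / modal), and the Lander–Waterman
  formula G = N·L/C. Reads/writes `samtools depth`-style 3-column TSV.
* **`gsize.congruence`** — assembly cross-consistency: shred assemblies into
  non-overlapping 240 bp synthetic reads, align them with a seed-and-extend
  local aligner (blastn-style scoring: match +1, mismatch −1, gap open 3,
  gap extend 2; E-value-calibrated score floor), and tabulate mean query
  cover % and the fraction of mapped reads above 95% identity. Alignment
  dumps use the BLAST `-outfmt 6` column order.
* **`gsize.cytometry`** — flow-cytometry fluorescence-ratio and Feulgen
  densitometry IOD conversion against internal standards (chicken 2.50 pg,
  human 7.00 pg, trout 5.2 pg, fruit fly 0.40 pg), calibration regression,
  pg ↔ Gb conversion (1 pg = 0.978 Gb), 1C/2C derivation and
  mean/SEM/CV summaries.
* **`gsize.report`** — missing-DNA gap, repeat/non-repeat partitioning of a
  cytometric genome, and consolidated multi-method comparison tables.

## Command line

One umbrella executable with a subcommand per stage:

```bash
gsize simulate-genome --config spec.yaml --seed 5 --out genome.fa --bed genome.bed
gsize simulate-reads  --genome genome.fa --coverage 30 --read-length 240 --seed 6 --out reads.fa
gsize collapse        --genome genome.fa --bed genome.bed --config spec.yaml --retain 1 --out asm.fa
gsize shred           asm.fa --fragment 240
gsize kmer-hist       reads.fa --k 21 --out hist.tsv
gsize kmer-size       --hist hist.tsv --cutoff auto
gsize depth-size      --depth depth.tsv --min-depth 2
gsize lw-size         --reads 1000000 --read-length 240 --modal 30
gsize congruence      --queries a.fa --refs b.fa --word 11
gsize cytometry fcm   --input fl.csv
gsize cytometry fiad  --input iod.csv
gsize cytometry convert --pg 3.08
gsize report          --assembly-mbp 700 --cyto-gb 1.5 --repeat-frac 0.6
```

The genome spec YAML looks like:

```yaml
unique_length: 400000
families:
  - {family_id: lineA, kind: dispersed, unit_length: 5000, copy_number: 40, divergence: 0.01}
  - {family_id: sat1, kind: tandem, unit_length: 250, copy_number: 400}
sex_pair: [50000, 40000]   # optional (Z, W)
```

All stochastic commands take an explicit `--seed`; fixed seed and config
give byte-identical outputs.

## Conventions

* Coordinates are 0-based half-open internally; the depth TSV (1-based) is
  the only exception, matching `samtools depth`.
* Rounding of reported pg/Gb values is half-away-from-zero at 2 decimals
  (3 for SEM); conversion to Gb happens after averaging across standards.
* k is restricted to odd values so no k-mer is its own reverse complement.
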