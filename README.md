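# ampliphase

Processing and haplotype inference for paired-end amplicon sequencing data.
`ampliphase` takes demultiplexed, annotated paired-end FASTQ files and turns
them into phased haplotypes for diploids, polyploids, and samples of unknown
ploidy:

1. **preprocess** — sliding-window quality trimming (default: PHRED 20,
   minimum length 100 bp), overlap-based read merging with an artificial
   N-join fallback for non-overlapping pairs, per-locus FASTA output with
   `>taxon|locus|uid` headers, plus a taxon-ploidy table and a per-locus
   sequencing-error table derived from PHRED scores.
2. **recluster** — iterative rounds of two-parent chimera filtering and
   abundance-sorted greedy centroid clustering (per taxon within each locus),
   producing clusters annotated with read counts (`;size=S`).
3. **crunch** — merging of gap-identical clusters, then maximum-likelihood
   haplotype inference: integer-partition multinomial likelihood when ploidy
   is known, a real-vs-error likelihood scan (default 10% relative increase
   cutoff) when it is not, and a haploid/consensus mode. Optional internal
   realignment (`--realign`) and column-occupancy cleaning (`--clean 0.33`).

A synthetic-data module (`ampliphase.simdata`) generates annotated read
pairs with known haplotypes, dosages, error rates, chimeras, and
non-overlapping pairs for testing.

## Command line

```sh
ampliphase simulate   --config sim.toml -o simdir
ampliphase preprocess -1 R1.fastq -2 R2.fastq -o predir [-q 20] [-l 100]
ampliphase recluster  -i predir/LocX.fasta -o cludir [--identities 0.997,0.995,0.990,0.997]
ampliphase crunch     -i cludir -t taxon_table.txt -e locus_err.txt -o hapdir \
                      [--haploid] [--unique] [--cutoff 0.10] [--realign] [--clean 0.33]
ampliphase pipeline   -1 R1.fastq -2 R2.fastq -o outdir [-t taxon_table.txt]
```

Ploidy is read from the two-column taxon table (`TaxA<TAB>4`; the literal
`None` marks unknown ploidy, the default after preprocessing). Edit the
table between `preprocess` and `crunch` to supply known ploidies.

Example simulation config (TOML):

```toml
[simulate]
divergence = 0.02
depth = 100
epsilon = 0.005
seed = 1

[simulate.taxa]
TaxA = 4          # tetraploid
TaxB = "None"     # unknown ploidy

[simulate.loci]
LocX = 300

[simulate.dosages]
"TaxA|LocX" = [2, 2]
"TaxB|LocX" = [1, 1]
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
format round-trips and invariants, independent brute-force oracles for the
partition/likelihood machinery, and stochastic parameter-recovery checks.

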