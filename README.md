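# phagetup

Computational characterization of fast-propagating white-plaque clones
arising in M13KE-based phage display libraries.

## The problem

Biopanning of an NEB Ph.D.-7 style library (NNK-encoded random 7-mers
displayed on pIII of the M13KE vector) can enrich **target-unrelated
peptides**: clones that dominate the output because they propagate
faster, not because they bind the target. One recurring genotype is a
white-plaque clone carrying a large genomic deletion that removes the
lacZ-alpha cassette — white on IPTG/X-gal plates, and easily mistaken
for contamination with environmental M13-like phage. This package
implements the complete computational workflow for characterizing such
a clone:

- **`ngs_pipeline`** — FASTQ amplicon reads → clean 7-mer peptide
  frequency tables. A read is clean iff its 21-nt peptide region
  translates to 7 canonical residues (no `*`) and the following 12-nt
  linker translates exactly to `GGGS`.
- **`cpa`** — competitive propagation assay summaries. Plaque-count
  based: white/blue ratio and white percentage per time point. NGS
  based: focal-clone share of clean reads over time, plus a per-interval
  log-odds fitness statistic
  *s* = [logit(*f*₂) − logit(*f*₁)] / (*t*₂ − *t*₁) in 1/min.
- **`provenance`** — library-vs-environment typing of Sanger-sequenced
  white plaques via the five signature nucleotides that distinguish
  M13KE from wild-type M13 (G1610, A1613, G1631, C1634, T1662), and
  extraction of the displayed peptide behind an anchor sequence.
- **`structural_variants`** — calls the single contiguous deletion
  between two assembled genome sequences from their longest common
  prefix/suffix, left-aligns it across breakpoint micro-homology
  (VCF convention), and annotates it against the genome model.
- **`genome_model`** — 1-based coordinate model of the 7222-nt M13KE
  genome (Ori 5487–5867, lacZ-alpha 6216–6695, signature positions),
  including the one-base offset between M13 and M13KE numbering.
- **`quantitation`** — qPCR genome copies/µL from a dsDNA mass
  concentration (gc/µL = [g/µL] / (bp × 607.4 + 157.9) × 6.02×10²³),
  standard-curve fitting/inversion, plaque-assay titers, ELISA binding
  ratios.
- **`synthetic`** — deterministic generators for all inputs (FASTQ read
  sets, pseudo-genomes, Sanger-like reads) with read-level ground truth,
  so the whole pipeline is testable without any sequencing data.

## Worked example

Simulate a competitive propagation assay (20,000 reads per time point,
focal clone WSLGYTG mixed at fractions 0.541/0.759/0.916), extract
peptides, and summarize the time course:

```sh
phagetup simulate --seed 5 --n-reads 20000 --out sim
phagetup extract-peptides --fastq sim/cpa_t0.fastq   --out extract_0
phagetup extract-peptides --fastq sim/cpa_t150.fastq --out extract_150
phagetup extract-peptides --fastq sim/cpa_t270.fastq --out extract_270
phagetup cpa-ngs --table 0:extract_0/frequencies.tsv \
                 --table 150:extract_150/frequencies.tsv \
                 --table 270:extract_270/frequencies.tsv \
                 --focal WSLGYTG --out course.tsv
```

which logs

```
INFO phagetup: sim/cpa_t0.fastq: 20000 reads, 18930 clean (5.4% removed)
INFO phagetup: time course: [(0.0, 54.1), (150.0, 75.5), (270.0, 91.6)];
  per-interval fitness (1/min): [0.00641, 0.01053]
```

The removal rate (~5%) reflects the configured read corruption (stop
codons in the peptide, mutated linkers); the focal percentages recover
the simulated mixture fractions to within binomial sampling error, and
the positive per-interval fitness quantifies the clone's propagation
advantage. Calling the deletion from the simulated genome pair:

```sh
phagetup call-deletion --ref sim/reference.fasta --alt sim/mutant.fasta \
                       --genome sim/genome.yaml --out del
cat del/deletion.tsv
```

```
start	end	length	homology_len	genome_fraction_percent
5879	6705	827	0	11.5

feature	relation	distance_nt
Ori	downstream_of	11
lacZalpha	contains	0
```

i.e. an 827-nt deletion (11.5% of the genome) that starts 11 nt
downstream of the origin of replication and removes lacZ-alpha entirely
— the genotype behind the white plaques.

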