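# Methods

This note documents the models, conventions and parameter choices behind
`phagetup`, and what the synthetic data do and do not establish about
real sequencing data.

## Coordinate model

All genome coordinates are 1-based and inclusive. The M13KE fixture is a
7222-nt genome with Ori at [5487, 5867], lacZ-alpha at [6216, 6695], the
observed white-clone deletion at [5879, 6705], and five signature
nucleotides (1610 G, 1613 A, 1631 G, 1634 C, 1662 T) distinguishing
M13KE from environmental wild-type M13. The gII feature start is modeled
at 6821, derived from the deletion ending 115 nt before gII
(6705 + 115 + 1); it is a derived coordinate, not an independently
established one. The M13→M13KE coordinate map is the identity up to
1564, undefined at 1565 (M13KE lacks the T found there in M13), and
pos − 1 from 1566 on. The wild-type M13 bases at the signature positions
are not modeled: provenance is judged by match/mismatch against the
M13KE base alone.

`feature_distance` reports the number of bases strictly between two
intervals (0 when they touch or overlap) plus a relation tag. Identical
intervals are tagged `overlaps`, not `contains`/`contained_in`; strict
containment in either direction gets its own tag. "Downstream" means
the query interval lies at higher coordinates than the feature.

## Read filtering and frequency tables

A read is parseable when it spans `peptide_offset + 33` nt: 21 nt of
peptide followed by 12 nt of linker. Checks run in a fixed order and the
first failure is the recorded reason: `too_short`, `stop_in_peptide`
(a `*` among the 7 translated residues), `invalid_aa_in_peptide`
(e.g. an N-containing codon, translated as `X`), `bad_linker`. Linker
validity is judged at the amino-acid level — any synonymous codons
translating to GGGS pass — because the validity rule is stated on
translated output; a strict-nucleotide mode (`ReadLayout.strict_linker_nt`)
is available since the original analysis script's behavior on synonymous
linker codons is not documented. Base qualities are parsed and ignored:
filtering is on translation validity only.

The read layout (peptide at 0-based offset 6 in a 53-nt read) is
explicit configuration: the amplicon architecture of the original
single-end 53-cycle run is not recoverable, so the generator defines the
layout and the pipeline consumes the same contract.

Percentages throughout (removal rates, relative abundances, CPA
percents, genome fractions) are rounded half-up to one decimal, matching
the precision at which such tables are conventionally reported. Internal
arithmetic is double precision; rounding is presentation-only.

## Competitive propagation assay

Plaque-count rows: ratio = white/blue titer (undefined when blue = 0);
percent = 100·white/(white+blue). For the published assay's final time
point the printed ratio (14.3) is inconsistent with its own titers
(2.7×10¹⁰/1.9×10⁸ ≈ 142.1) while the percent column is internally
consistent; the implementation always computes from titers and the test
suite asserts the percent for that row.

The per-interval relative fitness
s = [ln(f₂/(1−f₂)) − ln(f₁/(1−f₁))]/(t₂−t₁) (natural log, 1/min) is a
convenience statistic for "how fast is the focal clone taking over";
under logistic competition it is the selection coefficient per minute.
It is undefined (reported as `None`) when an endpoint sits at exactly
0% or 100%.

## Provenance thresholds

A Sanger read is called `library` when every covered signature position
matches the M13KE base and at least 3 of the 5 are covered;
`non_library` when ≥ 2 covered positions mismatch; `ambiguous`
otherwise. The thresholds are this package's choice (the original
determination was by visual alignment of eight clones with no stated
rule): requiring ≥ 3 covered positions prevents confident calls from
fragmentary reads, and requiring ≥ 2 mismatches for `non_library` keeps
a single Sanger miscall from flipping a call to "environmental". An `N`
counts as covered but neither matches nor mismatches. Reads given as
reverse complements produce identical calls via the `strand` argument.

Peptide extraction requires a unique exact anchor occurrence (both
strands searched), a GGGS-translating linker, and 7 canonical residues;
no general aligner is embedded.

## Deletion calling

Raw whole-genome sequencing reads for the white clone are not deposited;
the breakpoint interval is fully determined by the assembled sequences,
so the caller compares reference and mutant directly. With longest
common prefix P and suffix S, every placement of the
L = |ref| − |mut| deleted bases after a prefix p with
|mut| − S ≤ p ≤ P reproduces the mutant; the caller takes the smallest
such p (left-alignment, the VCF convention), reports
max(0, P + S − |mut|) as breakpoint micro-homology, and verifies the
call by excision and comparison. Anything not explainable as one
contiguous deletion raises `complex_variant` rather than guessing;
equal-length inputs raise `no_indel`. A brute-force oracle that
enumerates every valid excision confirms both the call and the
left-alignment on random instances in the test suite.

## Quantitation

Genome copies per µL from a dsDNA mass concentration use the dsDNA molar
mass approximation 607.4 g/mol per bp plus a 157.9 g/mol end correction
and Avogadro's number 6.02×10²³; the caller's dilution factor is applied
after the formula (multiplicatively, so the order is immaterial for a
pure scale factor, but it is documented as post-hoc). The qPCR standard
curve is an ordinary least-squares fit of Ct on log₁₀ copies, inverted
as copies = 10^((Ct − intercept)/slope). Plaque titers are
count × dilution / plated volume with a default plated volume of 0.01 mL
(10 µL); counts outside the 50–300 countable range are flagged, not
rejected. ELISA support is arithmetic only — reference-subtracted
(540 nm) 450-nm absorbance ratios of target over PBS wells; significance
testing is out of scope because replicate ODs are not available.

## Synthetic data

The generators define the conditions everything is tested under:

- **Reads**: 53-nt single-end, peptide at offset 6, three time points at
  0/150/270 min with focal fractions 0.541/0.759/0.916 (the NGS CPA
  trajectory of the white clone), 10⁴ reads per time point by default
  (larger runs scale it up). Background peptides are NNK draws (N·N·{G,T};
  32 codons, TAG the only stop) conditioned to be stop-free; corruption
  is then planted explicitly — an in-peptide stop codon with probability
  `stop_rate` or a non-synonymous linker codon with `linker_error_rate`.
  Defaults 0.01 + 0.038 total 4.8%, the removal rate observed at the
  first time point; the split between mechanisms is this package's
  choice since only the total is known. `exact_corruption` plants
  exactly round(rate·n) corrupted reads for deterministic bookkeeping.
  `sample_library_peptide` itself emits TAG-containing inserts (as NNK
  does) so the stop filter is exercised by the raw scheme too.
- **Genomes**: a uniformly random 7222-nt sequence with the fixture
  coordinates and signature bases planted, and a mutant lacking
  [5879, 6705]. Breakpoint flanks are constructed without micro-homology
  by default so the planted interval is the unique call; a
  `homology_len` flag plants homologous bases across the breakpoint to
  exercise left-alignment.
- **Sanger reads**: the 1130–1680 signature window (signatures planted,
  or ≥ 2 substituted for environmental origin) followed by a fixed
  15-nt anchor, the peptide's NNK-compatible coding sequence and the
  canonical linker; the anchor is guaranteed unique per read.

All generators are byte-deterministic under a fixed seed. What passing
tests show: the pipeline's bookkeeping, arithmetic and calling logic are
exact on data satisfying its structural assumptions, and mixture
fractions are recovered within binomial error. What they do not show:
robustness to real Illumina error profiles, quality-score structure,
chimeras, adapter read-through, or reference/sample divergence beyond a
single deletion — none of which the generators emulate.

## Problem sizes

Unit tests run at 10²–10⁴ reads; the mixture-recovery acceptance check
uses 10⁵ reads per time point (three binomial standard errors at the
clean-read count as the band); the deletion-caller oracle check uses
1,000 random genomes of length ≤ 200. The acceptance script works on the
full-size 7222-nt genome pair.

## Known limitations

- Only single contiguous deletions are callable; multi-variant genomes
  are refused.
- Provenance typing needs the read's placement (coordinate or anchor);
  there is no embedded aligner.
- The NGS pipeline does no demultiplexing, adapter trimming or
  quality filtering.
- The M13KE genome model covers only the features relevant here, with a
  synthetic random sequence standing in for the proprietary M13KE
  sequence; coordinate-level results are unaffected, sequence-level
  realism is not attempted.
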