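"""Synthetic inputs with the statistical structure the analysis assumes.

The study's raw sequencing data are not deposited, so every pipeline
stage is exercised on generated data instead:

* amplicon FASTQ reads (53 nt, single-end) carrying an NNK-encoded
  random 7-mer insert plus a synonymous GGGS linker, with a focal clone
  (WSLGYTG by default) mixed in at a per-time-point fraction that grows
  over the competitive propagation assay, and controllable read
  corruption (in-peptide stop codons, linker mutations);
* a 7222-nt pseudo-genome with the M13KE feature coordinates and
  signature bases planted in otherwise random sequence, plus its
  827-nt-deletion mutant;
* Sanger-like plaque reads spanning the signature window (1130-1680)
  with the peptide/linker cassette behind a fixed anchor.

Every generator is fully deterministic under a fixed seed and returns a
ground-truth record alongside the data, so downstream bookkeeping can be
checked read-for-read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._util import DomainError
from .genome_model import GenomeModel, m13ke_fixture, save_genome_config, write_fasta
from .ngs_pipeline import ReadLayout, translate_codons

FOCAL_PEPTIDE = "WSLGYTG"
DEFAULT_TIME_POINTS = (0.0, 150.0, 270.0)
# NGS-based CPA focal fractions at the three sampling times
DEFAULT_FOCAL_FRACTIONS = (0.541, 0.759, 0.916)

_BASES = np.array(list("ACGT"))

# NNK = N N {G,T}: 32 codons, one stop (TAG)
NNK_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "GT")
NNK_SENSE_CODONS = tuple(c for c in NNK_CODONS if c != "TAG")

# one NNK-compatible codon per amino acid, for reverse translation
AA_TO_NNK_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAG", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

LINKER_AA = "GGGS"
CANONICAL_LINKER_NT = "GGTGGAGGTTCG"
_G_CODONS = ("GGT", "GGC", "GGA", "GGG")
_S_CODONS = ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC")
_LINKER_CODON_CHOICES = (_G_CODONS, _G_CODONS, _G_CODONS, _S_CODONS)
# replacement codons whose product is neither G nor S (used to corrupt linkers)
_BAD_LINKER_CODONS = ("CGT", "AAA", "CAT", "TGG")
_STOP_CODONS = ("TAA", "TAG", "TGA")

SANGER_QUERY_START = 1130
SANGER_QUERY_END = 1680
DEFAULT_ANCHOR = "TCTCACTCTGGTACC"  # 15-nt fixed anchor upstream of the cassette


def reverse_translate(peptide: str) -> str:
    """One deterministic NNK-compatible coding sequence for a peptide."""
    try:
        return "".join(AA_TO_NNK_CODON[aa] for aa in peptide.upper())
    except KeyError as e:
        raise DomainError(f"not a canonical amino acid: {e.args[0]!r}") from None


def sample_nnk_codon(rng: np.random.Generator) -> str:
    """One codon from the NNK degenerate scheme (third base G or T)."""
    return NNK_CODONS[int(rng.integers(len(NNK_CODONS)))]


def sample_library_peptide(rng: np.random.Generator) -> str:
    """A 21-nt insert of 7 NNK codons; may contain the TAG stop codon."""
    idx = rng.integers(len(NNK_CODONS), size=7)
    return "".join(NNK_CODONS[int(i)] for i in idx)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for the NGS CPA read sets.

    Defaults reproduce the assay's conditions: three sampling times at
    0/150/270 min with focal fractions 0.541/0.759/0.916, 53-cycle
    single-end reads, and ~4.8% of reads corrupted (stop codons in the
    peptide plus linker mutations).
    """

    seed: int = 0
    n_reads: int = 10_000
    focal_peptide: str = FOCAL_PEPTIDE
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    focal_fractions: tuple[float, ...] = DEFAULT_FOCAL_FRACTIONS
    stop_rate: float = 0.01
    linker_error_rate: float = 0.038
    read_length: int = 53
    peptide_offset: int = 6
    exact_corruption: bool = False  # plant exactly round(rate*n) corrupted reads

    def __post_init__(self) -> None:
        if len(self.time_points) != len(self.focal_fractions):
            raise DomainError("time_points and focal_fractions must have equal length")
        for p in (*self.focal_fractions, self.stop_rate, self.linker_error_rate):
            if not 0.0 <= p <= 1.0:
                raise DomainError("probabilities must lie in [0, 1]")
        if self.stop_rate + self.linker_error_rate > 1.0:
            raise DomainError("corruption rates must sum to <= 1")
        if self.read_length < self.peptide_offset + 33:
            raise DomainError("read too short for peptide + linker at this offset")
        if len(self.focal_peptide) != 7:
            raise DomainError("focal peptide must be a 7-mer")

    @property
    def layout(self) -> ReadLayout:
        return ReadLayout(peptide_offset=self.peptide_offset)


@dataclass
class ReadTruth:
    peptide: str  # intended peptide before corruption
    is_focal: bool
    category: str  # clean | stop_in_peptide | bad_linker


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic reads."""

    time_points: tuple[float, ...]
    focal_fractions: tuple[float, ...]
    reads: dict[float, list[ReadTruth]] = field(default_factory=dict)

    def category_counts(self, time: float) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads[time]:
            out[r.category] = out.get(r.category, 0) + 1
        return out

    def clean_focal_fraction(self, time: float) -> float:
        """Realized focal fraction among clean reads at one time point."""
        clean = [r for r in self.reads[time] if r.category == "clean"]
        if not clean:
            raise DomainError("no clean reads at this time point")
        return sum(r.is_focal for r in clean) / len(clean)


@dataclass
class FastqSim:
    reads: dict[float, list[str]]
    truth: SimTruth
    paths: dict[float, Path] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(4, size=n)])


def _sample_linker(rng: np.random.Generator) -> str:
    return "".join(c[int(rng.integers(len(c)))] for c in _LINKER_CODON_CHOICES)


def generate_fastq(cfg: SimConfig, out_dir: str | Path | None = None) -> FastqSim:
    """Generate per-time-point FASTQ read sets plus read-level ground truth.

    Reads embed the peptide at ``cfg.peptide_offset`` followed by a
    synonymous GGGS linker, between fixed vector-context flanks shared by
    all reads of a run. Background (non-focal) peptides are NNK draws
    conditioned to be stop-free; in-peptide stops and linker mutations
    are then planted at the configured rates (exactly ``round(rate*n)``
    reads each when ``exact_corruption`` is set, else Bernoulli per read).
    """
    rng = np.random.default_rng(cfg.seed)
    flank5 = _random_seq(rng, cfg.peptide_offset)
    flank3 = _random_seq(rng, cfg.read_length - cfg.peptide_offset - 33)
    focal_nt = reverse_translate(cfg.focal_peptide)

    out_dir_p = Path(out_dir) if out_dir is not None else None
    if out_dir_p is not None:
        out_dir_p.mkdir(parents=True, exist_ok=True)

    truth = SimTruth(time_points=cfg.time_points, focal_fractions=cfg.focal_fractions)
    sim = FastqSim(reads={}, truth=truth)
    n = cfg.n_reads
    for t, frac in zip(cfg.time_points, cfg.focal_fractions):
        is_focal = rng.random(n) < frac
        if cfg.exact_corruption:
            n_stop = round(cfg.stop_rate * n)
            n_link = round(cfg.linker_error_rate * n)
            order = rng.permutation(n)
            category = np.full(n, "clean", dtype=object)
            category[order[:n_stop]] = "stop_in_peptide"
            category[order[n_stop : n_stop + n_link]] = "bad_linker"
        else:
            u = rng.random(n)
            category = np.full(n, "clean", dtype=object)
            category[u < cfg.stop_rate] = "stop_in_peptide"
            category[(u >= cfg.stop_rate) & (u < cfg.stop_rate + cfg.linker_error_rate)] = "bad_linker"

        # background peptides: stop-free NNK draws (31 sense codons)
        bg_idx = rng.integers(len(NNK_SENSE_CODONS), size=(n, 7))
        seqs: list[str] = []
        labels: list[ReadTruth] = []
        for i in range(n):
            if is_focal[i]:
                pep_nt = focal_nt
                pep_aa = cfg.focal_peptide
            else:
                pep_nt = "".join(NNK_SENSE_CODONS[int(j)] for j in bg_idx[i])
                pep_aa = translate_codons(pep_nt)
            linker_nt = _sample_linker(rng)
            cat = category[i]
            if cat == "stop_in_peptide":
                pos = int(rng.integers(7))
                stop = _STOP_CODONS[int(rng.integers(3))]
                pep_nt = pep_nt[: 3 * pos] + stop + pep_nt[3 * pos + 3 :]
            elif cat == "bad_linker":
                pos = int(rng.integers(4))
                bad = _BAD_LINKER_CODONS[int(rng.integers(len(_BAD_LINKER_CODONS)))]
                linker_nt = linker_nt[: 3 * pos] + bad + linker_nt[3 * pos + 3 :]
            seqs.append(flank5 + pep_nt + linker_nt + flank3)
            labels.append(ReadTruth(peptide=pep_aa, is_focal=bool(is_focal[i]), category=str(cat)))
        sim.reads[t] = seqs
        truth.reads[t] = labels
        if out_dir_p is not None:
            path = out_dir_p / f"cpa_t{t:g}.fastq"
            with open(path, "w") as fh:
                for i, s in enumerate(seqs):
                    fh.write(f"@t{t:g}_read{i}\n{s}\n+\n{'I' * len(s)}\n")
            sim.paths[t] = path
    return sim


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time_min\tread_index\tpeptide\tis_focal\tcategory\n")
        for t in truth.time_points:
            for i, r in enumerate(truth.reads[t]):
                fh.write(f"{t:g}\t{i}\t{r.peptide}\t{int(r.is_focal)}\t{r.category}\n")


@dataclass
class GenomeSim:
    reference: str
    mutant: str
    model: GenomeModel
    deletion: tuple[int, int]
    paths: dict[str, Path] = field(default_factory=dict)


def generate_genomes(
    seed: int, out_dir: str | Path | None = None, homology_len: int = 0
) -> GenomeSim:
    """A random 7222-nt pseudo-genome with M13KE coordinates, and its mutant.

    The reference carries the five signature bases at their fixture
    positions; the mutant lacks positions 5879-6705 (827 nt). By default
    the breakpoint flanks are constructed without micro-homology so the
    excised interval is the unique single-deletion explanation;
    ``homology_len`` plants that many bases of homology across the
    breakpoint to exercise left-alignment.
    """
    if not 0 <= homology_len <= 100:
        raise DomainError("homology_len must be in [0, 100]")
    rng = np.random.default_rng(seed)
    model0 = m13ke_fixture()
    seq = list(_random_seq(rng, model0.length))
    for sig in model0.signatures:
        seq[sig.position - 1] = sig.m13ke_base

    start, end = 5879, 6705  # 1-based inclusive deletion interval

    def _differs(i: int, j: int) -> None:
        # force seq[i] != seq[j] (0-based) by reassigning seq[j]
        if seq[i] == seq[j]:
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[j] = choices[int(rng.integers(3))]

    # suffix must stop at the deletion's right edge: base before the
    # deletion != last deleted base
    _differs(start - 2, end - 1)
    if homology_len:
        # copy homology_len bases from the deletion's left edge to just
        # after it, then break the match
        for k in range(homology_len):
            seq[end + k] = seq[start - 1 + k]
        _differs(start - 1 + homology_len, end + homology_len)
    else:
        # prefix must stop at the deletion's left edge
        _differs(start - 1, end)

    reference = "".join(seq)
    mutant = reference[: start - 1] + reference[end:]
    model = m13ke_fixture(sequence=reference)
    sim = GenomeSim(reference=reference, mutant=mutant, model=model, deletion=(start, end))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sim.paths["reference"] = out / "reference.fasta"
        sim.paths["mutant"] = out / "mutant.fasta"
        sim.paths["config"] = out / "genome.yaml"
        write_fasta(sim.paths["reference"], [("M13KE_synthetic", reference)])
        write_fasta(sim.paths["mutant"], [("M13KE_synthetic_del", mutant)])
        save_genome_config(model, sim.paths["config"])
    return sim


@dataclass
class SangerSim:
    reads: list[tuple[str, str]]  # (name, sequence)
    origin: str
    peptide: str
    anchor: str
    query_start: int = SANGER_QUERY_START
    path: Optional[Path] = None


def generate_sanger(
    seed: int,
    origin: str = "library",
    peptide: str = FOCAL_PEPTIDE,
    n_reads: int = 8,
    anchor: str = DEFAULT_ANCHOR,
    out_path: str | Path | None = None,
) -> SangerSim:
    """Sanger-like white-plaque reads over the signature window.

    Each read covers M13KE 1130-1680 (with the five signature bases
    planted for library origin, or >= 2 of them substituted for
    environmental origin) followed by the anchor, the peptide's coding
    sequence, and the canonical GGGS linker. The anchor is guaranteed to
    occur exactly once per read (counting both strands).
    """
    if origin not in ("library", "environmental"):
        raise DomainError("origin must be 'library' or 'environmental'")
    rng = np.random.default_rng(seed)
    model = m13ke_fixture()
    window_len = SANGER_QUERY_END - SANGER_QUERY_START + 1
    pep_nt = reverse_translate(peptide)
    from .provenance import reverse_complement  # local import avoids cycle at module load

    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        while True:
            window = list(_random_seq(rng, window_len))
            for sig in model.signatures:
                window[sig.position - SANGER_QUERY_START] = sig.m13ke_base
            if origin == "environmental":
                k = int(rng.integers(2, len(model.signatures) + 1))
                which = rng.choice(len(model.signatures), size=k, replace=False)
                for j in which:
                    sig = model.signatures[int(j)]
                    others = [b for b in "ACGT" if b != sig.m13ke_base]
                    window[sig.position - SANGER_QUERY_START] = others[int(rng.integers(3))]
            read = (
                "".join(window)
                + _random_seq(rng, 10)
                + anchor
                + pep_nt
                + CANONICAL_LINKER_NT
                + _random_seq(rng, 10)
            )
            if read.count(anchor) + reverse_complement(read).count(anchor) == 1:
                break
        reads.append((f"{origin}_plaque_{i}", read))
    sim = SangerSim(reads=reads, origin=origin, peptide=peptide, anchor=anchor)
    if out_path is not None:
        write_fasta(out_path, reads)
        sim.path = Path(out_path)
    return sim
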