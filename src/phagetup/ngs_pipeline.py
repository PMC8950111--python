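"""FASTQ -> clean peptide frequency table.

Amplicon reads from the display-cassette region of M13KE carry the 21-nt
insert encoding the displayed 7-mer peptide followed by the 12-nt
Gly-Gly-Gly-Ser linker that joins the peptide to pIII. A read is *clean*
when its 7 translated peptide residues are all canonical amino acids and
its linker region translates exactly to "GGGS"; everything else is
removed, with the reason recorded. Relative clone abundance is then a
percentage of clean reads.

Quality scores are parsed but ignored: validity is judged on translation
alone.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio.Data import CodonTable

from ._util import DomainError, round1

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
# codon -> amino acid, with '*' for the three stop codons; anything else
# (e.g. codons containing N) translates to 'X'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

REJECTION_REASONS = ("stop_in_peptide", "invalid_aa_in_peptide", "bad_linker", "too_short")


@dataclass(frozen=True)
class ReadLayout:
    """Where the peptide cassette sits within a read.

    ``peptide_offset`` is the 0-based position of the first peptide
    nucleotide. The 21-nt peptide is immediately followed by the 12-nt
    linker. When ``strict_linker_nt`` is set, the linker must match that
    exact nucleotide string; by default any synonymous codons translating
    to GGGS are accepted.
    """

    peptide_offset: int = 6
    peptide_len_nt: int = 21
    linker_len_nt: int = 12
    expected_linker_aa: str = "GGGS"
    strict_linker_nt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.peptide_offset < 0:
            raise DomainError("peptide_offset must be >= 0")
        if self.strict_linker_nt is not None and len(self.strict_linker_nt) != self.linker_len_nt:
            raise DomainError("strict_linker_nt must have linker_len_nt characters")

    @property
    def min_read_length(self) -> int:
        return self.peptide_offset + self.peptide_len_nt + self.linker_len_nt


def translate_codons(nt: str) -> str:
    """Translate a nucleotide string codon-by-codon (standard code).

    Stop codons become ``'*'``; codons containing ``N`` (or anything not
    in the standard table) become ``'X'``. Length must be a multiple of 3.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise DomainError(f"length {len(nt)} is not divisible by 3")
    return "".join(CODON_TO_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt), 3))


def process_read(seq: str, layout: ReadLayout = ReadLayout()) -> tuple[Optional[str], Optional[str]]:
    """Extract the displayed peptide from one read, or reject it.

    Returns ``(peptide, None)`` for a clean read and ``(None, reason)``
    otherwise, with reason one of :data:`REJECTION_REASONS`. Checks run in
    order: read long enough, no stop / no invalid residue in the peptide,
    linker translates to GGGS (or matches the strict nucleotide string).
    """
    seq = seq.upper()
    if len(seq) < layout.min_read_length:
        return None, "too_short"
    p0 = layout.peptide_offset
    peptide_nt = seq[p0 : p0 + layout.peptide_len_nt]
    linker_nt = seq[p0 + layout.peptide_len_nt : p0 + layout.peptide_len_nt + layout.linker_len_nt]
    peptide = translate_codons(peptide_nt)
    if "*" in peptide:
        return None, "stop_in_peptide"
    if not set(peptide) <= AMINO_ACIDS:
        return None, "invalid_aa_in_peptide"
    if layout.strict_linker_nt is not None:
        if linker_nt != layout.strict_linker_nt.upper():
            return None, "bad_linker"
    elif translate_codons(linker_nt) != layout.expected_linker_aa:
        return None, "bad_linker"
    return peptide, None


@dataclass
class FilterReport:
    """Clean/removed bookkeeping for one sample."""

    total_reads: int
    clean_reads: int
    removed_reads: int
    removal_reasons: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, total: int, removed: int, reasons: Optional[dict[str, int]] = None
    ) -> "FilterReport":
        if removed > total or total < 0 or removed < 0:
            raise DomainError("require 0 <= removed <= total")
        return cls(total, total - removed, removed, dict(reasons or {}))

    @property
    def removed_percent(self) -> float:
        if self.total_reads == 0:
            raise DomainError("no reads")
        return round1(100.0 * self.removed_reads / self.total_reads)

    @property
    def retained_percent(self) -> float:
        if self.total_reads == 0:
            raise DomainError("no reads")
        return round1(100.0 * self.clean_reads / self.total_reads)


@dataclass
class FrequencyTable:
    """Peptide -> clean-read count for one sample/time point."""

    sample_id: str
    counts: Counter = field(default_factory=Counter)
    clean_total: int = 0

    def items(self) -> list[tuple[str, int]]:
        """Counts in descending order, ties broken alphabetically."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def relative_abundance(self, peptide: str) -> float:
        return relative_abundance(self, peptide)


def relative_abundance(table: FrequencyTable, peptide: str) -> float:
    """Percent of clean reads carrying ``peptide``, to 1 decimal."""
    if table.clean_total <= 0:
        raise DomainError("clean_total must be > 0")
    return round1(100.0 * table.counts.get(peptide, 0) / table.clean_total)


def build_frequency_table(
    reads: Iterable[str],
    layout: ReadLayout = ReadLayout(),
    sample_id: str = "sample",
) -> tuple[FrequencyTable, FilterReport]:
    """Filter a stream of read sequences and tally clean peptides."""
    counts: Counter = Counter()
    reasons: Counter = Counter()
    total = 0
    for seq in reads:
        total += 1
        peptide, reason = process_read(seq, layout)
        if peptide is not None:
            counts[peptide] += 1
        else:
            reasons[reason] += 1
    if total == 0:
        raise DomainError("empty read stream")
    clean = sum(counts.values())
    table = FrequencyTable(sample_id=sample_id, counts=counts, clean_total=clean)
    report = FilterReport(total, clean, total - clean, dict(reasons))
    return table, report


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (plain or gzipped)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            fh.readline()  # qualities (unused)
            yield seq


def frequency_table_from_fastq(
    path: str | Path, layout: ReadLayout = ReadLayout(), sample_id: Optional[str] = None
) -> tuple[FrequencyTable, FilterReport]:
    sample_id = sample_id or Path(path).stem
    return build_frequency_table(read_fastq(path), layout, sample_id)


def write_frequency_table_tsv(table: FrequencyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tcount\tpercent_of_clean\n")
        for pep, n in table.items():
            fh.write(f"{pep}\t{n}\t{relative_abundance(table, pep)}\n")


def read_frequency_table_tsv(path: str | Path, sample_id: Optional[str] = None) -> FrequencyTable:
    counts: Counter = Counter()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("peptide\t"):
            raise DomainError(f"{path}: not a frequency-table TSV")
        for line in fh:
            pep, n, *_ = line.rstrip("\n").split("\t")
            counts[pep] = int(n)
    return FrequencyTable(
        sample_id=sample_id or Path(path).stem, counts=counts, clean_total=sum(counts.values())
    )


def write_filter_report_tsv(report: FilterReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("total_reads\tclean_reads\tremoved_reads\tremoved_percent\tretained_percent\n")
        fh.write(
            f"{report.total_reads}\t{report.clean_reads}\t{report.removed_reads}"
            f"\t{report.removed_percent}\t{report.retained_percent}\n"
        )
        fh.write("\n# removal reasons\n")
        for reason in REJECTION_REASONS:
            if reason in report.removal_reasons:
                fh.write(f"# {reason}\t{report.removal_reasons[reason]}\n")
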