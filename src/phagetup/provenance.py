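"""Library-vs-environment provenance of white plaques.

White plaques on IPTG/X-gal plates are conventionally blamed on
contamination with environmental M13-like phage. The M13KE vector,
however, differs from wild-type M13 at a handful of nucleotides; within
the Sanger-sequenced window (M13KE 1130-1680) five such signature
positions exist. A white plaque whose sequence carries the M13KE bases at
those positions derives from the library, not the environment.

This module types Sanger reads against the signature set and extracts the
displayed 7-mer peptide from reads that carry the peptide/linker
cassette.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._util import DomainError
from .genome_model import SignaturePosition
from .ngs_pipeline import AMINO_ACIDS, translate_codons

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProvenanceCall:
    """Outcome of typing one read against the signature positions.

    ``covered`` counts signature positions spanned by the read,
    ``matches`` those where the read shows the M13KE base. Verdicts:
    ``library`` when every covered position matches and at least 3 are
    covered; ``non_library`` when 2 or more covered positions mismatch;
    ``ambiguous`` otherwise (including no coverage at all). The
    thresholds tolerate isolated Sanger miscalls without flipping a call.
    """

    verdict: str
    matches: int
    covered: int
    per_position: dict[int, str]


def classify_origin(
    query: str,
    query_start: int,
    signatures: Sequence[SignaturePosition],
    strand: str = "+",
) -> ProvenanceCall:
    """Type a read placed at a known M13KE coordinate against the signatures.

    ``query_start`` is the 1-based M13KE coordinate of the read's
    leftmost base on the forward genome strand. Pass ``strand="-"`` for a
    read given as the reverse complement of that genome window; the call
    is identical either way. Bases read as ``N`` count as covered but
    neither match nor mismatch.
    """
    if query_start < 1:
        raise DomainError("query_start must be >= 1")
    if strand not in ("+", "-"):
        raise DomainError("strand must be '+' or '-'")
    query = query.upper()
    if not set(query) <= set("ACGTN"):
        raise DomainError("query may only contain A/C/G/T/N")
    if strand == "-":
        query = reverse_complement(query)
    end = query_start + len(query) - 1
    per_position: dict[int, str] = {}
    matches = mismatches = covered = 0
    for sig in signatures:
        if not query_start <= sig.position <= end:
            continue
        base = query[sig.position - query_start]
        per_position[sig.position] = base
        covered += 1
        if base == sig.m13ke_base:
            matches += 1
        elif base != "N":
            mismatches += 1
    if covered >= 3 and mismatches == 0 and matches == covered:
        verdict = "library"
    elif mismatches >= 2:
        verdict = "non_library"
    else:
        verdict = "ambiguous"
    return ProvenanceCall(verdict=verdict, matches=matches, covered=covered, per_position=per_position)


@dataclass(frozen=True)
class PeptideExtraction:
    peptide: Optional[str]
    reason: Optional[str]  # anchor_absent | anchor_ambiguous | truncated | bad_linker | invalid_peptide
    strand: Optional[str] = None


def extract_sanger_peptide(
    read: str,
    upstream_anchor: str,
    linker_aa: str = "GGGS",
) -> PeptideExtraction:
    """Pull the displayed 7-mer out of a Sanger read.

    Finds the unique exact occurrence of ``upstream_anchor`` on either
    strand, translates the following 21 nt as the peptide and the next
    12 nt as the linker, and returns the peptide only when the linker
    translates to ``linker_aa`` and the peptide is 7 canonical residues.
    """
    if len(upstream_anchor) < 12:
        raise DomainError("anchor must be at least 12 nt")
    read = read.upper()
    anchor = upstream_anchor.upper()
    hits: list[tuple[str, int]] = []
    for strand, seq in (("+", read), ("-", reverse_complement(read))):
        i = seq.find(anchor)
        while i != -1:
            hits.append((strand, i))
            i = seq.find(anchor, i + 1)
    if not hits:
        return PeptideExtraction(None, "anchor_absent")
    if len(hits) > 1:
        return PeptideExtraction(None, "anchor_ambiguous")
    strand, i = hits[0]
    seq = read if strand == "+" else reverse_complement(read)
    cassette = seq[i + len(anchor) : i + len(anchor) + 33]
    if len(cassette) < 33:
        return PeptideExtraction(None, "truncated", strand)
    peptide = translate_codons(cassette[:21])
    linker = translate_codons(cassette[21:33])
    if linker != linker_aa:
        return PeptideExtraction(None, "bad_linker", strand)
    if not set(peptide) <= AMINO_ACIDS:
        return PeptideExtraction(None, "invalid_peptide", strand)
    return PeptideExtraction(peptide, None, strand)


def classify_fasta_records(
    records: Iterable[tuple[str, str]],
    query_start: int,
    signatures: Sequence[SignaturePosition],
) -> list[tuple[str, ProvenanceCall]]:
    """classify_origin over (name, sequence) pairs sharing one placement."""
    return [(name, classify_origin(seq, query_start, signatures)) for name, seq in records]
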