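"""Single-deletion calling from a pair of assembled genome sequences.

The white clone's genotype is a single large deletion relative to the
M13KE reference. Given the assembled reference and mutant sequences, the
breakpoints of a single contiguous deletion are fully determined by the
longest common prefix and suffix of the two strings; when breakpoint
micro-homology makes the placement ambiguous, the call is left-aligned
(smallest start coordinate), the convention VCF uses. Anything that is
not explainable as one contiguous deletion is refused rather than
guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ._util import DomainError, round1
from .genome_model import GenomeFeature, GenomeModel, feature_distance


class NoIndelError(DomainError):
    """Reference and mutant have equal length (no deletion to call)."""


class ComplexVariantError(DomainError):
    """Sequences do not differ by a single contiguous deletion."""


@dataclass(frozen=True)
class DeletionCall:
    """A contiguous deletion: 1-based inclusive reference interval."""

    start: int
    end: int
    length: int
    homology_len: int = 0
    left_aligned: bool = True


@dataclass(frozen=True)
class DeletionAnnotation:
    call: DeletionCall
    affected_features: list[tuple[GenomeFeature, str, int]]  # (feature, relation, distance)
    genome_fraction_percent: float


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def call_single_deletion(reference: str, mutant: str) -> DeletionCall:
    """Call the left-aligned single contiguous deletion turning reference into mutant.

    With P = longest common prefix and S = longest common suffix, every
    valid placement deletes ``length = |ref| - |mut|`` bases starting after
    some prefix p with ``|mut| - S <= p <= P``; the leftmost such p gives
    the left-aligned call, and ``P + S - |mut|`` (when positive) is the
    breakpoint micro-homology. The call is verified by excising the
    interval and comparing with the mutant.
    """
    reference, mutant = reference.upper(), mutant.upper()
    for name, seq in (("reference", reference), ("mutant", mutant)):
        if not set(seq) <= set("ACGT"):
            raise DomainError(f"{name} may only contain A/C/G/T")
    if len(mutant) == len(reference):
        raise NoIndelError("no_indel: sequences have equal length")
    if len(mutant) > len(reference):
        raise DomainError("mutant is longer than reference; only deletions are supported")
    length = len(reference) - len(mutant)
    p = _common_prefix_len(reference, mutant)
    s = _common_prefix_len(reference[::-1], mutant[::-1])
    p0 = max(0, len(mutant) - s)
    if p0 > p:
        raise ComplexVariantError("complex_variant: not a single contiguous deletion")
    start, end = p0 + 1, p0 + length
    if reference[:p0] + reference[p0 + length :] != mutant:
        raise ComplexVariantError("complex_variant: reconstruction check failed")
    return DeletionCall(
        start=start,
        end=end,
        length=length,
        homology_len=max(0, p + s - len(mutant)),
        left_aligned=True,
    )


def annotate_deletion(call: DeletionCall, genome: GenomeModel) -> DeletionAnnotation:
    """Relate the call to every genome feature and to total genome size."""
    if not 1 <= call.start <= call.end <= genome.length:
        raise DomainError(
            f"call [{call.start}, {call.end}] outside genome of length {genome.length}"
        )
    affected = []
    for f in genome.features:
        dist, rel = feature_distance((call.start, call.end), f)
        affected.append((f, rel, dist))
    return DeletionAnnotation(
        call=call,
        affected_features=affected,
        genome_fraction_percent=round1(100.0 * call.length / genome.length),
    )


def deletion_to_vcf(call: DeletionCall, reference: str, chrom: str = "M13KE") -> str:
    """Minimal VCF-style record (anchor-base REF/ALT convention, 1-based)."""
    if call.start > 1:
        pos = call.start - 1
        ref_allele = reference[pos - 1 : call.end]
        alt_allele = reference[pos - 1]
    else:  # deletion at position 1: anchor on the base after the deletion
        pos = 1
        ref_allele = reference[0 : call.end + 1]
        alt_allele = reference[call.end]
    return f"{chrom}\t{pos}\t.\t{ref_allele}\t{alt_allele}\t.\tPASS\tSVTYPE=DEL;SVLEN=-{call.length}"


def write_annotation_tsv(ann: DeletionAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\thomology_len\tgenome_fraction_percent\n")
        c = ann.call
        fh.write(f"{c.start}\t{c.end}\t{c.length}\t{c.homology_len}\t{ann.genome_fraction_percent}\n")
        fh.write("\nfeature\trelation\tdistance_nt\n")
        for feat, rel, dist in ann.affected_features:
            fh.write(f"{feat.name}\t{rel}\t{dist}\n")
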