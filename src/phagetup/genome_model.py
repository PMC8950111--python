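"""Coordinate model of the M13KE phage genome.

M13KE is the M13mp19-derived cloning vector behind the NEB Ph.D. display
libraries. It carries a lacZ-alpha cassette near the phage origin of
replication (Ori), which makes library plaques blue on IPTG/X-gal plates.
This module holds the genome's named feature intervals, the five signature
nucleotides that distinguish library-derived M13KE from environmental
wild-type M13, and the one-base coordinate offset between the two genomes.

All coordinates are 1-based and inclusive, matching how positions are
conventionally printed for this vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from Bio import SeqIO

from ._util import DomainError

_NUCS = set("ACGT")


@dataclass(frozen=True)
class GenomeFeature:
    """A named interval on the genome (1-based, inclusive)."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DomainError(
                f"feature {self.name!r}: require 1 <= start <= end, got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise DomainError(f"feature {self.name!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SignaturePosition:
    """One of the nucleotides that distinguish M13KE from wild-type M13.

    ``m13_base`` (the environmental-phage base at the homologous position)
    is optional: classification of plaque origin is done by match/mismatch
    against the M13KE base alone.
    """

    position: int
    m13ke_base: str
    m13_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DomainError("signature position must be >= 1")
        if self.m13ke_base not in _NUCS:
            raise DomainError(f"m13ke_base must be one of A/C/G/T, got {self.m13ke_base!r}")
        if self.m13_base is not None and self.m13_base not in _NUCS:
            raise DomainError(f"m13_base must be one of A/C/G/T, got {self.m13_base!r}")


@dataclass
class GenomeModel:
    """Genome length plus named features and signature positions.

    The nucleotide sequence is optional so that purely coordinate-level
    logic (annotation, offsets, signature typing against reads with known
    placement) works without any particular sequence on hand; the
    synthetic-data module supplies a random sequence with the true
    coordinates when one is needed.
    """

    length: int
    features: list[GenomeFeature] = field(default_factory=list)
    signatures: list[SignaturePosition] = field(default_factory=list)
    sequence: Optional[str] = None
    name: str = "genome"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DomainError("genome length must be positive")
        for f in self.features:
            if f.end > self.length:
                raise DomainError(
                    f"feature {f.name!r} [{f.start}, {f.end}] exceeds genome length {self.length}"
                )
        for s in self.signatures:
            if s.position > self.length:
                raise DomainError(f"signature position {s.position} exceeds genome length")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise DomainError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
            if not set(self.sequence) <= (_NUCS | {"N"}):
                raise DomainError("sequence may only contain A/C/G/T/N")

    def feature(self, name: str) -> GenomeFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


# Fixture coordinates for M13KE (7222 nt). The deletion interval is the
# large intergenic deletion observed in the fast-propagating white clone:
# it starts 11 nt downstream of Ori and removes the whole lacZ-alpha gene
# plus 10 nt downstream. gII's start is derived from the deletion ending
# 115 nt before gII (6705 + 115 + 1 = 6821).
M13KE_LENGTH = 7222
M13KE_ORI = GenomeFeature("Ori", 5487, 5867)
M13KE_LACZ_ALPHA = GenomeFeature("lacZalpha", 6216, 6695)
M13KE_OBSERVED_DELETION = GenomeFeature("observed_deletion", 5879, 6705)
M13KE_GII = GenomeFeature("gII", 6821, 7222)

M13KE_SIGNATURES = (
    SignaturePosition(1610, "G"),
    SignaturePosition(1613, "A"),
    SignaturePosition(1631, "G"),
    SignaturePosition(1634, "C"),
    SignaturePosition(1662, "T"),
)


def m13ke_fixture(sequence: Optional[str] = None) -> GenomeModel:
    """The M13KE coordinate fixture (optionally with a sequence attached)."""
    return GenomeModel(
        length=M13KE_LENGTH,
        features=[M13KE_ORI, M13KE_LACZ_ALPHA, M13KE_OBSERVED_DELETION, M13KE_GII],
        signatures=list(M13KE_SIGNATURES),
        sequence=sequence,
        name="M13KE",
    )


def m13_to_m13ke_coord(pos: int) -> Optional[int]:
    """Map a wild-type M13 coordinate to its M13KE coordinate.

    M13KE lacks the T found at M13 position 1565, so M13KE numbering runs
    one lower from there on. Returns ``None`` for position 1565 itself
    (the deleted base has no M13KE image).
    """
    if pos < 1:
        raise DomainError(f"position must be >= 1, got {pos}")
    if pos <= 1564:
        return pos
    if pos == 1565:
        return None
    return pos - 1


def feature_distance(
    call_interval: tuple[int, int], feature: GenomeFeature
) -> tuple[int, str]:
    """Gap (nt strictly between) and relation of an interval to a feature.

    Relations: ``upstream_of`` / ``downstream_of`` (disjoint; the tag
    describes where the interval lies relative to the feature),
    ``contains`` (interval strictly covers the feature), ``contained_in``
    (feature strictly covers the interval), ``overlaps`` (any other
    overlap, including identical intervals). Distance is 0 whenever the
    two touch or overlap.
    """
    start, end = call_interval
    if not 1 <= start <= end:
        raise DomainError(f"malformed interval [{start}, {end}]")
    if end < feature.start:
        return feature.start - end - 1, "upstream_of"
    if start > feature.end:
        return start - feature.end - 1, "downstream_of"
    # overlapping in some way
    if (start, end) == (feature.start, feature.end):
        return 0, "overlaps"
    if start <= feature.start and end >= feature.end:
        return 0, "contains"
    if start >= feature.start and end <= feature.end:
        return 0, "contained_in"
    return 0, "overlaps"


def save_genome_config(model: GenomeModel, path: str | Path, fasta: str | Path | None = None) -> None:
    """Write the coordinate model as YAML; optionally write the sequence as FASTA."""
    doc = {
        "name": model.name,
        "length": model.length,
        "features": [
            {"name": f.name, "start": f.start, "end": f.end, "strand": f.strand}
            for f in model.features
        ],
        "signatures": [
            {"position": s.position, "m13ke_base": s.m13ke_base, **({"m13_base": s.m13_base} if s.m13_base else {})}
            for s in model.signatures
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    if fasta is not None:
        if model.sequence is None:
            raise DomainError("model has no sequence to write")
        write_fasta(fasta, [(model.name, model.sequence)])


def load_genome_config(path: str | Path, fasta: str | Path | None = None) -> GenomeModel:
    """Load a coordinate model from YAML, optionally attaching a FASTA sequence."""
    doc = yaml.safe_load(Path(path).read_text())
    sequence = None
    if fasta is not None:
        records = list(SeqIO.parse(str(fasta), "fasta"))
        if len(records) != 1:
            raise DomainError(f"expected exactly one FASTA record in {fasta}")
        sequence = str(records[0].seq)
    return GenomeModel(
        length=int(doc["length"]),
        features=[
            GenomeFeature(f["name"], int(f["start"]), int(f["end"]), f.get("strand", "+"))
            for f in doc.get("features", [])
        ],
        signatures=[
            SignaturePosition(int(s["position"]), s["m13ke_base"], s.get("m13_base"))
            for s in doc.get("signatures", [])
        ],
        sequence=sequence,
        name=doc.get("name", "genome"),
    )


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as a plain FASTA file, 70 columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
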