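"""Sequence and annotation I/O and the coordinate contract shared by the pipeline.

All internal coordinates are 0-based half-open. GenBank input (1-based
inclusive) is converted on ingest; human-facing reports convert back to
1-based inclusive; BED output stays 0-based half-open per the BED standard.
Sequences are uppercased on ingest; IUPAC ambiguity codes are retained and
treated as mismatching any different symbol downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: GenBank feature keys mapped to internal feature kinds.
_GENBANK_KIND = {
    "CDS": "cds",
    "gene": "other",
    "tRNA": "trna",
    "rRNA": "rrna",
    "D-loop": "control_region",
    "repeat_region": "repeat_region",
    "misc_feature": "other",
}


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FeatureKind(str, Enum):
    cds = "cds"
    trna = "trna"
    rrna = "rrna"
    control_region = "control_region"
    repeat_region = "repeat_region"
    other = "other"


class Strand(str, Enum):
    heavy = "heavy"
    light = "light"


@dataclass
class Feature:
    """An annotated interval on a genome, 0-based half-open."""

    name: str
    kind: FeatureKind
    start: int
    end: int
    strand: Strand = Strand.heavy

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("feature name must be non-empty")
        if self.start >= self.end:
            raise ValidationError(
                f"feature {self.name!r}: start {self.start} >= end {self.end}"
            )


@dataclass
class GenomeRecord:
    """One input sequence with optional feature annotations.

    ``circular`` marks the molecule topology; the sequence is stored
    linearized at the input's position 0, and wrap-aware operations say so
    explicitly.
    """

    id: str
    seq: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        for pos, ch in enumerate(self.seq):
            if ch not in IUPAC_DNA:
                raise ValidationError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} at position {pos}"
                )
        for f in self.features:
            if f.end > len(self.seq) and not self.circular:
                raise ValidationError(
                    f"record {self.id!r}: feature {f.name!r} extends past sequence end"
                )

    def __len__(self) -> int:
        return len(self.seq)


def _feature_from_genbank(sf) -> Feature | None:
    kind = _GENBANK_KIND.get(sf.type)
    if kind is None:
        return None
    quals = sf.qualifiers
    name = (
        quals.get("gene", [None])[0]
        or quals.get("product", [None])[0]
        or quals.get("note", [None])[0]
        or sf.type
    )
    strand = Strand.light if sf.location.strand == -1 else Strand.heavy
    # Biopython already exposes GenBank locations 0-based half-open.
    return Feature(
        name=str(name),
        kind=FeatureKind(kind),
        start=int(sf.location.start),
        end=int(sf.location.end),
        strand=strand,
    )


def read_genomes(path: str | Path, format: str = "fasta") -> list[GenomeRecord]:
    """Read a multi-entry FASTA or GenBank flat file into GenomeRecords.

    GenBank coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; sequences are uppercased. A non-IUPAC
    character raises :class:`ValidationError` naming the record and position.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    if not path.exists():
        raise OSError(f"no such file: {path}")
    records: list[GenomeRecord] = []
    for entry in SeqIO.parse(str(path), format):
        features: list[Feature] = []
        circular = False
        if format == "genbank":
            circular = entry.annotations.get("topology", "") == "circular"
            for sf in entry.features:
                feat = _feature_from_genbank(sf)
                if feat is not None:
                    features.append(feat)
        records.append(
            GenomeRecord(id=entry.id, seq=str(entry.seq), circular=circular, features=features)
        )
    if not records:
        raise OSError(f"no records parsed from {path}")
    return records


def write_genomes(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records as multi-entry FASTA (features are not serialized)."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(Path(path)), "fasta")


def write_region_bed(
    record_id: str,
    intervals: Sequence[tuple[str, int, int]],
    path: str | Path,
    seq_len: int | None = None,
) -> None:
    """Write labelled intervals as BED (0-based half-open, chrom/start/end/name).

    ``seq_len``, when given, bounds-checks intervals against the sequence.
    """
    for label, start, end in intervals:
        if start < 0 or end < start:
            raise ValidationError(f"interval {label!r}: negative or inverted ({start}, {end})")
        if seq_len is not None and end > seq_len:
            raise ValidationError(
                f"interval {label!r}: end {end} beyond sequence length {seq_len}"
            )
    with open(path, "w") as fh:
        for label, start, end in intervals:
            fh.write(f"{record_id}\t{start}\t{end}\t{label}\n")


def to_report_coords(start: int, end: int) -> tuple[int, int]:
    """Convert an internal 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def from_report_coords(first: int, last: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to internal 0-based half-open."""
    return first - 1, last
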