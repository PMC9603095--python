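"""FASTA / TSV input-output and the coordinate conventions used package-wide.

All residue coordinates in this package are 1-based and inclusive, matching
the conventions of biologist-facing domain annotation tools.  Conversion to
Python slices happens only at slicing boundaries, never in stored data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The 20 canonical amino acids, alphabetical; the package-wide column order.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letters tolerated on input.  ``X`` (unknown residue) is accepted
#: but excluded from every frequency denominator downstream.
INPUT_ALPHABET = set(CANONICAL_ALPHABET) | {"X"}


class SequenceError(ValueError):
    """Malformed sequence input (bad residue, duplicate id, empty file)."""


class AnnotationError(ValueError):
    """Malformed topology annotation input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    the full header is kept in ``description``.
    """

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive residue interval, ``1 <= start <= end``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}]: "
                "need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def slice(self, residues: str) -> str:
        """Extract the interval from a residue string (bounds-checked)."""
        if self.end > len(residues):
            raise AnnotationError(
                f"interval [{self.start}, {self.end}] exceeds sequence "
                f"length {len(residues)}"
            )
        return residues[self.start - 1 : self.end]

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class TopologyAnnotation:
    """Per-sequence topology: signal peptide, TM segments, kinase domain.

    ``source`` records whether the annotation came from an external tool
    (re-expressed as TSV) or from the built-in hydropathy heuristics.
    """

    sp: bool = False
    sp_cleavage: Optional[int] = None
    tm_segments: list[Interval] = field(default_factory=list)
    kinase_domain: Optional[Interval] = None
    source: str = "external"

    def __post_init__(self) -> None:
        self.tm_segments = sorted(self.tm_segments)
        for a, b in zip(self.tm_segments, self.tm_segments[1:]):
            if a.overlaps(b):
                raise AnnotationError(f"overlapping TM segments {a} and {b}")
        if (
            self.sp_cleavage is not None
            and self.tm_segments
            and self.sp_cleavage >= self.tm_segments[0].start
        ):
            raise AnnotationError(
                "signal-peptide cleavage site must precede the first TM segment"
            )


def _validate_residues(record_id: str, residues: str) -> str:
    residues = residues.upper()
    if not residues:
        raise SequenceError(f"record {record_id!r} has an empty sequence")
    bad = set(residues) - INPUT_ALPHABET
    if bad:
        raise SequenceError(
            f"record {record_id!r} contains illegal residue(s) "
            f"{''.join(sorted(bad))!r}"
        )
    return residues


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a protein FASTA file into :class:`SequenceRecord` objects.

    Wrapped sequence lines are concatenated and uppercased.  Duplicate ids,
    empty files and residues outside ``ACDEFGHIKLMNPQRSTVWYX`` are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _validate_residues(rec.id, str(rec.seq))
        records.append(
            SequenceRecord(id=rec.id, residues=residues, description=rec.description)
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def _parse_interval(text: str) -> Interval:
    try:
        start_s, end_s = text.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise AnnotationError(f"malformed interval {text!r}") from exc
    if end < start:
        raise AnnotationError(f"interval end < start in {text!r}")
    return Interval(start, end)


ANNOTATION_COLUMNS = ["id", "sp", "tm_segments", "kinase_domain"]


def read_annotations(path: str | Path) -> dict[str, TopologyAnnotation]:
    """Read the topology-annotation TSV: id, sp (Y/N), tm_segments, kinase_domain.

    ``tm_segments`` is a semicolon-separated list of ``start-end`` pairs and
    may be empty; ``kinase_domain`` is a single ``start-end`` or empty.
    Missing optional fields mean: no signal peptide / no TM / no kinase domain.
    """
    annotations: dict[str, TopologyAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "id":
                continue
            row = list(row) + [""] * (4 - len(row))
            seq_id, sp_s, tm_s, kin_s = row[0], row[1], row[2], row[3]
            tm = [_parse_interval(t) for t in tm_s.split(";") if t.strip()]
            kinase = _parse_interval(kin_s) if kin_s.strip() else None
            annotations[seq_id] = TopologyAnnotation(
                sp=sp_s.strip().upper() == "Y",
                tm_segments=tm,
                kinase_domain=kinase,
                source="external",
            )
    return annotations


def write_annotations(
    annotations: dict[str, TopologyAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for seq_id, ann in annotations.items():
            writer.writerow(
                [
                    seq_id,
                    "Y" if ann.sp else "N",
                    ";".join(f"{t.start}-{t.end}" for t in ann.tm_segments),
                    f"{ann.kinase_domain.start}-{ann.kinase_domain.end}"
                    if ann.kinase_domain
                    else "",
                ]
            )


#: Column schema of the per-sequence prediction report.
REPORT_COLUMNS = [
    "Accession",
    "SP",
    "TM",
    "RLP-NRLP",
    "RLP-NRLP Probability",
    "RLP-RLK",
    "RLP-RLK Probability",
    "RLP-Subfamily",
    "RLP-Subfamily Probability",
    "Classification",
    "Decision Probability",
]

_PROB_COLUMNS = {c for c in REPORT_COLUMNS if c.endswith("Probability")}


def write_prediction_report(rows: Sequence[dict], path: str | Path) -> None:
    """Write prediction rows as TSV; probabilities printed with 4 decimals."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for row in rows:
            out = []
            for col in REPORT_COLUMNS:
                value = row[col]
                if col in _PROB_COLUMNS:
                    value = f"{float(value):.4f}"
                out.append(value)
            writer.writerow(out)
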