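"""Sequence and annotation I/O, plus the coordinate conventions used package-wide.

All coordinates are 1-based and inclusive on both ends, matching the
GenBank/GFF3 convention, so intervals read from or written to GFF3 need no
conversion. Sequences are uppercased on read; soft-masking is ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class GFFParseError(ValueError):
    """Malformed GFF3 row (bad coordinates or strand)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (one FASTA entry)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise AlphabetError(
                f"record {self.id!r}: disallowed character {self.seq[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based, inclusive, stranded interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.start}..{self.end} on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and not (
            self.end < other.start or other.end < self.start
        )

    def overlap_length(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def slice_of(self, seq: str) -> str:
        """Extract this interval from a full-length forward-strand sequence.

        The returned string is always the forward-strand segment; callers
        reverse-complement when they need the minus-strand reading.
        """
        if self.end > len(seq):
            raise ValueError(
                f"interval {self.start}..{self.end} exceeds sequence length {len(seq)}"
            )
        return seq[self.start - 1 : self.end]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene (or CDS) with its genomic location."""

    id: str
    location: Interval
    product: str = ""


def read_fasta(path: str | Path, alphabet: frozenset | None = NUCLEOTIDE_ALPHABET) -> list[SequenceRecord]:
    """Read a FASTA file into uppercased :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file to read.
    alphabet
        Permitted characters after uppercasing; ``None`` disables the check
        (used for amino-acid references).

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header, or an entry is empty,
        or an id is duplicated.
    AlphabetError
        If a sequence contains a character outside the alphabet.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                break

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has no sequence")
        if alphabet is not None:
            bad = set(seq) - alphabet
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise AlphabetError(
                    f"{path}: record {rec.id!r}: disallowed character "
                    f"{seq[pos]!r} at position {pos + 1}"
                )
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        if alphabet is None:
            records.append(_AARecord(rec.id, seq, desc))
        else:
            records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


@dataclass(frozen=True)
class _AARecord(SequenceRecord):
    """Amino-acid record: same shape as SequenceRecord, alphabet unchecked."""

    def __post_init__(self) -> None:  # skip nucleotide alphabet validation
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")


#: Public name for in-memory amino-acid records (alphabet unchecked).
ProteinRecord = _AARecord


def read_protein_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read an amino-acid FASTA (no nucleotide alphabet restriction)."""
    return read_fasta(path, alphabet=None)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gff(path: str | Path, feature_types: Sequence[str] = ("CDS", "gene")) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Only rows whose type is in ``feature_types`` are consumed. Coordinates
    are kept verbatim (GFF3 is already 1-based inclusive). The product
    string is taken from the ``product`` attribute, falling back to ``Note``.
    """
    genes: list[GeneModel] = []
    counter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(f"{path}: line {lineno}: expected 9 columns")
            if fields[2] not in feature_types:
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GFFParseError(f"{path}: line {lineno}: {exc}") from exc
            if feat.end < feat.start:
                raise GFFParseError(
                    f"{path}: line {lineno}: end {feat.end} < start {feat.start}"
                )
            if feat.strand not in ("+", "-"):
                raise GFFParseError(
                    f"{path}: line {lineno}: unknown strand {feat.strand!r}"
                )
            counter += 1
            gene_id = feat.attributes.get("ID", [f"gene{counter}"])[0]
            product = (
                feat.attributes.get("product", [None])[0]
                or feat.attributes.get("Note", [None])[0]
                or ""
            )
            genes.append(
                GeneModel(
                    id=gene_id,
                    location=Interval(feat.seqid, feat.start, feat.end, feat.strand),
                    product=product,
                )
            )
    return genes


REPORT_COLUMNS = [
    "seq_id",
    "system_id",
    "component",
    "start",
    "end",
    "strand",
    "a_substitutions",
    "total_substitutions",
    "non_a_fraction",
    "partner_coordinates",
    "completeness",
]


def _system_rows(systems) -> list[dict]:
    rows = []
    for sys_ in systems:
        base = {"system_id": sys_.system_id, "completeness": sys_.completeness}
        if sys_.rt is not None:
            rows.append(
                dict(
                    base,
                    seq_id=sys_.rt.location.seq_id,
                    component="RT",
                    start=sys_.rt.location.start,
                    end=sys_.rt.location.end,
                    strand=sys_.rt.location.strand,
                    a_substitutions="",
                    total_substitutions="",
                    non_a_fraction="",
                    partner_coordinates=sys_.rt.ref_id,
                )
            )
        for pair in sys_.pairs:
            rows.append(
                dict(
                    base,
                    seq_id=pair.tr.seq_id,
                    component="TR",
                    start=pair.tr.start,
                    end=pair.tr.end,
                    strand=pair.tr.strand,
                    a_substitutions=pair.a_subs,
                    total_substitutions=pair.profile.total_subs,
                    non_a_fraction=f"{pair.non_a_frac:.4f}",
                    partner_coordinates=f"{pair.vr.start}..{pair.vr.end}",
                )
            )
            rows.append(
                dict(
                    base,
                    seq_id=pair.vr.seq_id,
                    component="VR",
                    start=pair.vr.start,
                    end=pair.vr.end,
                    strand=pair.vr.strand,
                    a_substitutions=pair.a_subs,
                    total_substitutions=pair.profile.total_subs,
                    non_a_fraction=f"{pair.non_a_frac:.4f}",
                    partner_coordinates=f"{pair.tr.start}..{pair.tr.end}",
                )
            )
        if sys_.reference_tr is not None and not sys_.pairs:
            loc = sys_.reference_tr.location
            rows.append(
                dict(
                    base,
                    seq_id=loc.seq_id,
                    component="TR",
                    start=loc.start,
                    end=loc.end,
                    strand=loc.strand,
                    a_substitutions="",
                    total_substitutions="",
                    non_a_fraction="",
                    partner_coordinates=sys_.reference_tr.ref_tr_id,
                )
            )
        for call in sys_.targets:
            loc = call.gene.location
            rows.append(
                dict(
                    base,
                    seq_id=loc.seq_id,
                    component="target",
                    start=loc.start,
                    end=loc.end,
                    strand=loc.strand,
                    a_substitutions="",
                    total_substitutions="",
                    non_a_fraction="",
                    partner_coordinates=f"{call.vr.start}..{call.vr.end}",
                )
            )
    return rows


def write_report(systems, path: str | Path, format: str = "tsv") -> None:
    """Write assembled systems to disk, one row/feature per component.

    ``format`` is ``tsv`` (fixed 11-column header) or ``gff3``. Coordinates
    round-trip exactly: re-reading a GFF3 report yields identical intervals.
    """
    rows = _system_rows(systems)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS, delimiter="\t")
            writer.writeheader()
            for row in rows:
                writer.writerow(row)
    elif format == "gff3":
        type_map = {"RT": "CDS", "TR": "repeat_region", "VR": "repeat_region", "target": "gene"}
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, row in enumerate(rows, 1):
                attrs = [
                    f"ID={row['system_id']}.{row['component']}.{i}",
                    f"system_id={row['system_id']}",
                    f"component={row['component']}",
                    f"completeness={row['completeness']}",
                ]
                if row["partner_coordinates"]:
                    attrs.append(f"partner={row['partner_coordinates']}")
                if row["a_substitutions"] != "":
                    attrs.append(f"a_substitutions={row['a_substitutions']}")
                    attrs.append(f"total_substitutions={row['total_substitutions']}")
                    attrs.append(f"non_a_fraction={row['non_a_fraction']}")
                fh.write(
                    "\t".join(
                        [
                            row["seq_id"],
                            "dgrfinder",
                            type_map[row["component"]],
                            str(row["start"]),
                            str(row["end"]),
                            ".",
                            row["strand"],
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown report format {format!r}")
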