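"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates inside the toolkit are 0-based half-open; conversion
to and from 1-based closed conventions (GFF3, RepeatMasker) happens only
here, at the I/O boundary. Sequences are stored in the DNA alphabet: U is
normalized to T and lowercase to uppercase at ingest. N is permitted and
never matches anything downstream.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "FeatureInterval",
    "read_sequences",
    "write_sequences",
    "read_features",
    "write_features",
    "write_report",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = frozenset({"gene", "exon", "utr3", "utr5", "repeat", "peak", "other"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over {A,C,G,T,N} with optional Sanger qualities."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureInterval:
    """A strand-aware genomic annotation in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    name: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"feature {self.name!r}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.name!r}: end {self.end} not greater than start {self.start}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.name!r}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "FeatureInterval") -> bool:
        """At-least-one-base overlap on the same contig (half-open arithmetic)."""
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def _normalize_seq(raw: str, *, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{where}: non-ACGTUN symbol(s) {sorted(bad)}")
    return seq


def read_sequences(path: str | Path, format: str = "fasta") -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file in file order.

    Lowercase is uppercased and U becomes T. Malformed records (quality
    length mismatch, empty sequence) raise ``ValueError`` naming the
    location.
    """
    path = Path(path)
    if format == "fasta":
        yield from _read_fasta(path)
    elif format == "fastq":
        yield from _read_fastq(path)
    else:
        raise ValueError(f"unknown sequence format {format!r}")


def _read_fasta(path: Path) -> Iterator[SequenceRecord]:
    seen: set[str] = set()
    with open(path) as handle:
        for ordinal, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            if len(rec.seq) == 0:
                raise ValueError(f"{path}: record #{ordinal} ({rec.id!r}) is empty")
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            seq = _normalize_seq(str(rec.seq), where=f"{path}: record #{ordinal}")
            yield SequenceRecord(id=rec.id, seq=seq)


def _read_fastq(path: Path) -> Iterator[SequenceRecord]:
    seen: set[str] = set()
    n_done = 0
    with open(path) as handle:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                n_done = i
                line = 4 * i + 1
                rid = title.split()[0]
                if not seq:
                    raise ValueError(f"{path}: line {line}: empty sequence")
                if len(qual) != len(seq):
                    raise ValueError(
                        f"{path}: line {line}: quality length {len(qual)} != "
                        f"sequence length {len(seq)}"
                    )
                if rid in seen:
                    raise ValueError(f"{path}: line {line}: duplicate read id {rid!r}")
                seen.add(rid)
                yield SequenceRecord(
                    id=rid,
                    seq=_normalize_seq(seq, where=f"{path}: line {line}"),
                    qual=qual,
                )
        except ValueError as exc:
            # Biopython reports truncated/misaligned records without location;
            # the failing record follows the last one successfully parsed.
            if str(exc).startswith(str(path)):
                raise
            line = 4 * (n_done + 1) + 1 if seen else 1
            raise ValueError(f"{path}: line {line}: malformed FASTQ: {exc}") from exc


def write_sequences(records: Iterable[SequenceRecord], path: str | Path,
                    format: str = "fasta", width: int = 70) -> None:
    """Write FASTA (wrapped) or FASTQ; the inverse of :func:`read_sequences`."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            if format == "fasta":
                handle.write(f">{rec.id}\n")
                for i in range(0, len(rec.seq), width):
                    handle.write(rec.seq[i : i + width] + "\n")
            elif format == "fastq":
                qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
                handle.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
            else:
                raise ValueError(f"unknown sequence format {format!r}")


def read_features(path: str | Path, dialect: str) -> list[FeatureInterval]:
    """Read genomic features from BED (3-6 col), GFF3, or RepeatMasker ".out".

    BED is kept 0-based half-open as-is; GFF3 start is shifted by -1;
    RepeatMasker rows become kind="repeat" with the class/family column as
    ``class_label``.
    """
    path = Path(path)
    if dialect == "bed":
        return list(_read_bed(path))
    if dialect == "gff3":
        return list(_read_gff3(path))
    if dialect == "rmout":
        return list(_read_rmout(path))
    raise ValueError(f"unknown feature dialect {dialect!r}")


def _read_bed(path: Path) -> Iterator[FeatureInterval]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: bad interval [{start}, {end})"
                )
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 else "."
            yield FeatureInterval(
                contig=cols[0], start=start, end=end, strand=strand,
                kind="other", name=name,
            )


_GFF3_KIND = {
    "gene": "gene",
    "mRNA": "gene",
    "exon": "exon",
    "three_prime_UTR": "utr3",
    "five_prime_UTR": "utr5",
    "repeat_region": "repeat",
}


def _parse_gff3_attrs(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.split(";"):
        part = part.strip()
        if part and "=" in part:
            key, _, value = part.partition("=")
            attrs[key] = value
    return attrs


def _read_gff3(path: Path) -> Iterator[FeatureInterval]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(
                    f"{path}: line {lineno}: bad 1-based interval [{start1}, {end1}]"
                )
            attrs = _parse_gff3_attrs(cols[8])
            name = attrs.get("Name") or attrs.get("ID") or ""
            yield FeatureInterval(
                contig=cols[0],
                start=start1 - 1,  # 1-based closed -> 0-based half-open
                end=end1,
                strand=cols[6] if cols[6] in ("+", "-") else ".",
                kind=_GFF3_KIND.get(cols[2], "other"),
                name=name,
                class_label=attrs.get("biotype", ""),
            )


def _read_rmout(path: Path) -> Iterator[FeatureInterval]:
    """RepeatMasker ".out": whitespace-delimited table after a 3-line header."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            cols = line.split()
            if not cols or not cols[0].isdigit():
                continue  # header / blank lines
            if len(cols) < 11:
                raise ValueError(f"{path}: line {lineno}: truncated RepeatMasker row")
            contig, start1, end1 = cols[4], int(cols[5]), int(cols[6])
            if start1 < 1 or end1 < start1:
                raise ValueError(
                    f"{path}: line {lineno}: bad interval [{start1}, {end1}]"
                )
            strand = "+" if cols[8] == "+" else "-" if cols[8] in ("-", "C") else "."
            yield FeatureInterval(
                contig=contig,
                start=start1 - 1,
                end=end1,
                strand=strand,
                kind="repeat",
                name=cols[9],
                class_label=cols[10],
            )


def write_features(features: Sequence[FeatureInterval], path: str | Path, dialect: str) -> None:
    """Write features as BED6 or GFF3 (inverse of :func:`read_features`)."""
    path = Path(path)
    if dialect == "bed":
        lines = [
            f"{f.contig}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}"
            for f in features
        ]
    elif dialect == "gff3":
        kind_back = {v: k for k, v in _GFF3_KIND.items() if v != "gene" or k == "gene"}
        lines = ["##gff-version 3"]
        for f in features:
            attrs = f"ID={f.name}" if f.name else "ID=feat"
            if f.class_label:
                attrs += f";biotype={f.class_label}"
            lines.append(
                f"{f.contig}\tsrnakit\t{kind_back.get(f.kind, f.kind)}\t"
                f"{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}"
            )
    else:
        raise ValueError(f"unknown feature dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


def write_report(rows: Sequence[Mapping[str, object]], path: str | Path,
                 columns: Sequence[str] | None = None) -> None:
    """Write a TSV report: header line, one row per mapping, bit-stable.

    All rows must share one schema; ``columns`` fixes the column order
    (defaults to the first row's insertion order).
    """
    path = Path(path)
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("empty report needs an explicit column list")
        columns = list(rows[0].keys())
    schema = set(columns)
    buf = _io.StringIO()
    buf.write("\t".join(columns) + "\n")
    for i, row in enumerate(rows):
        if set(row.keys()) != schema:
            raise ValueError(f"row {i} schema {sorted(row)} != {sorted(schema)}")
        buf.write("\t".join(_format_cell(row[c]) for c in columns) + "\n")
    path.write_text(buf.getvalue())


def _format_cell(value: object) -> str:
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)
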