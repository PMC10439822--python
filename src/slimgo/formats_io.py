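"""Readers and writers for every on-disk format the pipeline touches.

Formats: multi-record nucleotide FASTA, 12-column tabular hit files
(BLAST ``-outfmt 6`` layout), GO slim mapping TSVs (two dialects), and
the per-gene-set summary tables.

All writers are deterministic and all reader/writer pairs round-trip:
``write(read(write(x)))`` is byte-identical to ``write(x)``.  Floats are
serialized with :func:`repr`, which is shortest-round-trip in Python 3.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "HitRecord",
    "SlimMapping",
    "SlimCountTable",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_slim_mapping",
    "write_slim_mapping",
    "read_table",
    "write_table",
]

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, message: str, path: str | os.PathLike | None = None,
                 line: int | None = None):
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = str(path) if path is not None else None
        self.line = line


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; ``id`` is the first whitespace token of the header."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class HitRecord:
    """One row of 12-column tabular search output (BLAST ``-outfmt 6``)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue!r}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"percent identity {self.percent_identity!r} outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError(
                f"alignment length {self.alignment_length!r} < 1")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise ValueError("negative mismatch/gapopen count")


@dataclass
class SlimMapping:
    """Map from a reference subject key to its GO slim categories."""

    entries: dict[str, frozenset[str]]
    level_key: str = "gene"          # "gene" (gene-model ids) or "locus"
    source_dialect: str = "canonical"

    def __post_init__(self) -> None:
        for key, cats in self.entries.items():
            if not cats:
                raise ValueError(f"key {key!r} maps to an empty category set")
            if any(not c for c in cats):
                raise ValueError(f"key {key!r} has an empty category label")

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, key: str) -> frozenset[str]:
        return self.entries.get(key, frozenset())


@dataclass
class SlimCountTable:
    """One gene set's category -> value table with coverage metadata.

    ``kind`` is ``raw`` (non-negative integer counts) or ``frequency``
    (fractions that sum to 1 when any annotation exists); ``level`` is
    ``gene`` or ``locus``.
    """

    label: str
    level: str
    kind: str
    values: dict[str, float] = field(default_factory=dict)
    n_input_sequences: int = 0
    n_with_best_hit: int = 0
    n_annotated: int = 0

    def __post_init__(self) -> None:
        if self.level not in ("gene", "locus"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.kind not in ("raw", "frequency"):
            raise ValueError(f"unknown kind {self.kind!r}")

    def total(self) -> float:
        return sum(self.values.values())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Raises :class:`FormatError` on an empty file, a duplicate id, or an
    empty sequence.  The record count is the coverage denominator used
    downstream, so every header yields exactly one record.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}", path)
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() \
            if rec.description.startswith(rec.id) else rec.description
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r}", path)
        records.append(SequenceRecord(rec.id, desc, seq))
    if not records:
        raise FormatError("no FASTA records found", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular hits

def _fmt(value: float) -> str:
    return repr(float(value))


def read_tabular_hits(path: str | os.PathLike) -> list[HitRecord]:
    """Read a 12-column tab-delimited hits file, preserving row order.

    Row order matters downstream: it is the final tie-break key in
    best-hit selection.  Empty lines are skipped; an empty file yields
    an empty list.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"expected 12 tab-delimited columns, found {len(fields)}",
                    path, lineno)
            try:
                hits.append(HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                ))
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
    return hits


def write_tabular_hits(records: Iterable[HitRecord],
                       path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join([
                r.query_id, r.subject_id, _fmt(r.percent_identity),
                str(r.alignment_length), str(r.mismatches), str(r.gap_opens),
                str(r.q_start), str(r.q_end), str(r.s_start), str(r.s_end),
                _fmt(r.evalue), _fmt(r.bitscore),
            ]) + "\n")


# ---------------------------------------------------------------------------
# GO slim mapping dialects

def read_slim_mapping(path: str | os.PathLike,
                      dialect: str = "canonical",
                      excluded_categories: Iterable[str] = (),
                      key_column: int = 0,
                      term_column: int = 1,
                      level_key: str = "gene") -> SlimMapping:
    """Read a subject-key -> GO slim category mapping file.

    ``canonical`` dialect: two tab-separated columns (key, category),
    repeated keys accumulate into a set.  ``tair`` dialect: multi-column
    TSV where ``key_column``/``term_column`` select the fields and lines
    starting with ``!`` are comments (the TAIR distribution convention).

    Pairs whose category is in ``excluded_categories`` are dropped; keys
    left with no surviving category are absent from the result.
    """
    if dialect not in ("canonical", "tair"):
        raise ValueError(f"unknown mapping dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    excluded = set(excluded_categories)
    entries: dict[str, set[str]] = {}
    min_cols = 2 if dialect == "canonical" else max(key_column, term_column) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if dialect == "tair" and line.startswith("!"):
                continue
            fields = line.split("\t")
            if dialect == "canonical" and len(fields) != 2:
                raise FormatError(
                    f"expected 2 columns, found {len(fields)}", path, lineno)
            if len(fields) < min_cols:
                raise FormatError(
                    f"expected at least {min_cols} columns, found {len(fields)}",
                    path, lineno)
            key = fields[key_column] if dialect == "tair" else fields[0]
            term = fields[term_column] if dialect == "tair" else fields[1]
            if not key or not term:
                raise FormatError("empty key or category", path, lineno)
            if term in excluded:
                continue
            entries.setdefault(key, set()).add(term)
    if not entries:
        raise FormatError("mapping file yielded no entries", path)
    return SlimMapping(
        entries={k: frozenset(v) for k, v in entries.items()},
        level_key=level_key,
        source_dialect=dialect,
    )


def write_slim_mapping(mapping: SlimMapping, path: str | os.PathLike) -> None:
    """Write a mapping in the canonical 2-column dialect, sorted for determinism."""
    with open(path, "w") as fh:
        for key in sorted(mapping.entries):
            for cat in sorted(mapping.entries[key]):
                fh.write(f"{key}\t{cat}\n")


# ---------------------------------------------------------------------------
# Summary tables

_META_FIELDS = ("label", "level", "kind",
                "n_input_sequences", "n_with_best_hit", "n_annotated")


def write_table(table: SlimCountTable, path: str | os.PathLike) -> None:
    """Write a summary table as TSV: '#' metadata lines, header, rows.

    Raw counts are written as integers, frequencies via repr() so the
    table round-trips losslessly.
    """
    with open(path, "w") as fh:
        for name in _META_FIELDS:
            fh.write(f"# {name}={getattr(table, name)}\n")
        fh.write(f"GO_slim_category\t{table.label}\n")
        for cat in sorted(table.values):
            v = table.values[cat]
            cell = str(int(v)) if table.kind == "raw" else repr(float(v))
            fh.write(f"{cat}\t{cell}\n")


def read_table(path: str | os.PathLike) -> SlimCountTable:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    values: dict[str, float] = {}
    header_seen = False
    label = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                fields = line.split("\t")
                if fields[0] != "GO_slim_category" or len(fields) != 2:
                    raise FormatError(
                        "missing 'GO_slim_category<TAB><label>' header",
                        path, lineno)
                label = fields[1]
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"expected 2 columns, found {len(fields)}", path, lineno)
            try:
                num = float(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric cell {fields[1]!r}", path, lineno) from exc
            values[fields[0]] = num
    if not header_seen:
        raise FormatError("missing header row", path)
    kind = meta.get("kind", "raw")
    if kind == "raw":
        values = {k: int(v) for k, v in values.items()}
    return SlimCountTable(
        label=meta.get("label", label),
        level=meta.get("level", "gene"),
        kind=kind,
        values=values,
        n_input_sequences=int(meta.get("n_input_sequences", 0)),
        n_with_best_hit=int(meta.get("n_with_best_hit", 0)),
        n_annotated=int(meta.get("n_annotated", 0)),
    )
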