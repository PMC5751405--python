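"""Readers and writers for the plain-text formats the binner consumes.

Inputs are assembled contigs in FASTA and a two-column tab-separated coverage
table (contig id, mean reads per base), as produced by summarising a read
alignment. Outputs are an assignment TSV (contig id, bin label) and one FASTA
per bin. Assembly and read mapping are out of scope: the coverage table is
consumed as-is.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

#: label for contigs left out of every bin (DBSCAN noise, dissolved bins,
#: filtered contigs); distinct from all bin labels (which are >= 0)
UNCLASSIFIED = -1

#: string used for UNCLASSIFIED in assignment TSVs
UNCLASSIFIED_NAME = "unclassified"


@dataclass(frozen=True)
class ContigRecord:
    """One assembled sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ContigRecord: id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"ContigRecord {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_contigs(path: str | os.PathLike) -> list[ContigRecord]:
    """Read contigs from a FASTA file (wrapped or unwrapped records).

    The record id is the header token up to the first whitespace; sequences
    are uppercased.

    Raises
    ------
    ValueError
        On duplicate ids (naming the offending id) or an empty file.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(ContigRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _parse_cov_fields(line: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 2:
        fields = line.split()
    return fields


def read_coverage(path: str | os.PathLike) -> dict[str, float]:
    """Read a two-column (contig id, coverage) tab-separated table.

    A header line is auto-detected: if the second field of the first
    non-blank line is non-numeric it is skipped.

    Raises
    ------
    ValueError
        On malformed lines or negative/non-numeric coverage (with the
        1-based line number), or if no data rows are present.
    """
    coverages: dict[str, float] = {}
    first_data = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = _parse_cov_fields(raw)
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            cid, val = fields
            try:
                cov = float(val)
            except ValueError:
                if first_data:
                    first_data = False  # header line
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coverage {val!r}"
                ) from None
            first_data = False
            if cov < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage {cov}")
            if cid in coverages:
                raise ValueError(f"{path}:{lineno}: duplicate contig id {cid!r}")
            coverages[cid] = cov
    if not coverages:
        raise ValueError(f"no coverage rows found in {path}")
    return coverages


def read_truth(path: str | os.PathLike) -> dict[str, str]:
    """Read a ground-truth table (contig id, genome id), optional header."""
    truth: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = _parse_cov_fields(raw)
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            if lineno == 1 and fields[0].lower() in {"contig", "contig_id", "id"}:
                continue
            truth[fields[0]] = fields[1]
    if not truth:
        raise ValueError(f"no truth rows found in {path}")
    return truth


def write_assignments(
    assignment: Mapping[str, int] | pd.Series, path: str | os.PathLike
) -> None:
    """Write an assignment TSV (contig_id, bin) with 'unclassified' for noise."""
    if isinstance(assignment, pd.Series):
        items = list(assignment.items())
    else:
        items = list(assignment.items())
    with open(path, "w") as fh:
        fh.write("contig_id\tbin\n")
        for cid, label in items:
            name = UNCLASSIFIED_NAME if label == UNCLASSIFIED else str(int(label))
            fh.write(f"{cid}\t{name}\n")


def read_assignments(path: str | os.PathLike) -> dict[str, int]:
    """Read an assignment TSV written by :func:`write_assignments`."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = _parse_cov_fields(raw)
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            cid, label = fields
            if lineno == 1 and label.lower() in {"bin", "bin_label", "label"}:
                continue
            out[cid] = (
                UNCLASSIFIED
                if label.lower() == UNCLASSIFIED_NAME
                else int(label)
            )
    return out


def _write_fasta(records: Iterable[ContigRecord], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bins(
    contigs: Sequence[ContigRecord],
    assignment: Mapping[str, int] | pd.Series,
    outdir: str | os.PathLike,
) -> list[Path]:
    """Write one FASTA per bin plus ``unclassified.fasta``.

    Files are named ``bin_000.fasta``, ``bin_001.fasta``, ... by descending
    bin size; ties broken by the smallest contig id in the bin. Returns the
    list of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(assignment, pd.Series):
        assignment = assignment.to_dict()
    missing = [c.id for c in contigs if c.id not in assignment]
    if missing:
        raise ValueError(
            "assignment does not cover contigs: " + ", ".join(missing[:10])
        )
    by_label: dict[int, list[ContigRecord]] = {}
    for c in contigs:
        by_label.setdefault(int(assignment[c.id]), []).append(c)
    unclassified = by_label.pop(UNCLASSIFIED, [])
    ordered = sorted(
        by_label.values(), key=lambda recs: (-len(recs), min(r.id for r in recs))
    )
    written = []
    for i, recs in enumerate(ordered):
        path = outdir / f"bin_{i:03d}.fasta"
        _write_fasta(recs, path)
        written.append(path)
    upath = outdir / "unclassified.fasta"
    _write_fasta(unclassified, upath)
    written.append(upath)
    return written


def write_feature_table(features: pd.DataFrame, path: str | os.PathLike) -> None:
    """Serialise a feature table to TSV (canonical 4-mer column headers)."""
    features.to_csv(path, sep="\t", index_label="id")
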