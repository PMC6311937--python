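"""Reading and writing the formats the framework touches.

FASTA (plain and gapped) goes through Biopython's SeqIO. Sequences are
upper-cased on read and ``.`` gaps are normalized to ``-`` so that the rest
of the package sees one canonical form. Label tables are two-column TSV
(id, family). Distance matrices round-trip through either a TSV dialect
(header row of ids) or the PHYLIP square dialect (leading count line).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Union

import numpy as np
from Bio import SeqIO

from .containers import GAP, AlignmentMatrix, DistanceMatrix, ProteinSequence, SequenceSet
from .errors import AmbiguousLabelError, ContractError, FormatError

PathLike = Union[str, Path]

DIALECTS = ("tsv", "phylip-square")


def _parse_fasta_records(handle) -> list[tuple[str, str]]:
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace(".", GAP)))
    return records


def read_fasta(path: PathLike, aligned: bool = False) -> SequenceSet | AlignmentMatrix:
    """Read a FASTA file as a :class:`SequenceSet` (``aligned=False``) or an
    :class:`AlignmentMatrix` (``aligned=True``).

    Gap characters in an unaligned file are a format error; ragged rows in an
    aligned file are a format error. ``.`` is accepted as a gap and
    normalized to ``-``; residues are upper-cased.
    """
    path = Path(path)
    with open(path) as fh:
        records = _parse_fasta_records(fh)
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate id(s) {dupes}")
    if aligned:
        try:
            return AlignmentMatrix(ids, [r[1] for r in records])
        except FormatError as e:
            raise FormatError(f"{path}: {e}") from e
    seqs = []
    for sid, res in records:
        if GAP in res:
            raise FormatError(f"{path}: sequence {sid!r} contains gaps but aligned=False")
        seqs.append(ProteinSequence(sid, res))
    return SequenceSet(seqs)


def write_fasta(obj: SequenceSet | AlignmentMatrix, path: PathLike, width: int = 60) -> None:
    """Write sequences or alignment rows as FASTA with *width*-column wrapping."""
    if isinstance(obj, AlignmentMatrix):
        items = list(zip(obj.ids, obj.rows))
    else:
        items = [(s.id, s.residues) for s in obj]
    with open(path, "w") as fh:
        for sid, seq in items:
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_labels(path: PathLike, header: str | bool = "auto") -> dict[str, str]:
    """Read a two-column TSV (id, family) into an id → family map.

    ``header`` may be True, False, or ``"auto"`` (skip the first row when it
    reads as ``id<TAB>family``, case-insensitive). An id listed under two
    different families raises :class:`AmbiguousLabelError`; that mirrors the
    exclusion rule applied during dataset assembly, where such sequences are
    dropped rather than guessed at.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected 2 tab-separated columns, got {len(parts)}")
            rows.append([p.strip() for p in parts])
    if not rows:
        raise FormatError(f"{path}: empty label table")
    if header is True or (
        header == "auto" and [c.lower() for c in rows[0]] == ["id", "family"]
    ):
        rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: label table has a header but no data rows")
    labels: dict[str, str] = {}
    for sid, fam in rows:
        if sid in labels and labels[sid] != fam:
            raise AmbiguousLabelError(
                f"{path}: id {sid!r} listed under both {labels[sid]!r} and {fam!r}"
            )
        labels[sid] = fam
    return labels


def write_labels(labels: Mapping[str, str], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for sid, fam in labels.items():
            w.writerow([sid, fam])


def distance_matrix_to_string(m: DistanceMatrix, dialect: str = "tsv", precision: int = 10) -> str:
    """Format *m* as TSV (header row of ids) or PHYLIP square (count line first).

    *precision* decimal places guarantee re-reads agree within 1e-9.
    """
    if dialect not in DIALECTS:
        raise ContractError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    fmt = f"%.{precision}f"
    lines = []
    if dialect == "phylip-square":
        lines.append(str(len(m)))
    else:
        lines.append("id\t" + "\t".join(m.ids))
    for sid, row in zip(m.ids, m.values):
        lines.append(sid + "\t" + "\t".join(fmt % v for v in row))
    return "\n".join(lines) + "\n"


def write_distance_matrix(
    m: DistanceMatrix, path: PathLike, dialect: str = "tsv", precision: int = 10
) -> None:
    """Write *m* to *path*; see :func:`distance_matrix_to_string` for dialects."""
    with open(path, "w") as fh:
        fh.write(distance_matrix_to_string(m, dialect=dialect, precision=precision))


def read_distance_matrix(path: PathLike, dialect: str = "auto") -> DistanceMatrix:
    """Read a distance matrix written by :func:`write_distance_matrix`.

    ``dialect="auto"`` sniffs PHYLIP square from a single-integer first line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty distance matrix file")
    first = lines[0].split("\t")
    if dialect == "auto":
        dialect = "phylip-square" if len(first) == 1 and first[0].strip().isdigit() else "tsv"
    if dialect == "phylip-square":
        n = int(first[0])
        body = lines[1:]
        if len(body) != n:
            raise FormatError(f"{path}: expected {n} rows, found {len(body)}")
    elif dialect == "tsv":
        body = lines[1:]
    else:
        raise ContractError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    ids, rows = [], []
    for ln in body:
        parts = ln.split("\t")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    try:
        return DistanceMatrix(ids, np.array(rows))
    except ContractError as e:
        raise FormatError(f"{path}: {e}") from e
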