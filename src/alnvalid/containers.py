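"""Core in-memory containers: sequences, alignments, distance matrices.

Every container validates its own invariants on construction, so downstream
code can assume ids are unique, alignment rows are rectangular and distance
matrices are symmetric with a zero diagonal. Row/column order of a
:class:`DistanceMatrix` always equals the order of the originating
:class:`SequenceSet`; ids are carried alongside the values everywhere to
prevent silent misalignment of labels and distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ContractError, FormatError

GAP = "-"

#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity / rare codes accepted in input: B (D/N), Z (E/Q), X (any),
#: U (selenocysteine).
EXTENDED_RESIDUES = STANDARD_RESIDUES | frozenset("XBZU")


@dataclass(frozen=True)
class ProteinSequence:
    """An identified, ungapped amino-acid sequence, optionally family-labeled."""

    id: str
    residues: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ContractError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise ContractError(f"sequence {self.id!r} has empty residues")
        bad = set(self.residues) - EXTENDED_RESIDUES
        if bad:
            raise ContractError(
                f"sequence {self.id!r} contains invalid residue(s) {sorted(bad)!r} "
                "(gaps are not allowed in unaligned sequences)"
            )

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """An ordered collection of :class:`ProteinSequence` with unique ids.

    The iteration order is stable and defines the row/column order of any
    matrix computed from the set.
    """

    def __init__(self, sequences: Sequence[ProteinSequence]):
        seqs = list(sequences)
        ids = [s.id for s in seqs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence id(s): {dupes}")
        self._sequences = seqs
        self._index = {s.id: k for k, s in enumerate(seqs)}

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self._sequences]

    def __len__(self) -> int:
        return len(self._sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self._sequences)

    def __getitem__(self, key: int | str) -> ProteinSequence:
        if isinstance(key, str):
            return self._sequences[self._index[key]]
        return self._sequences[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        """New set restricted to *ids*, keeping this set's order."""
        wanted = set(ids)
        missing = wanted - set(self._index)
        if missing:
            raise ContractError(f"unknown sequence id(s): {sorted(missing)}")
        return SequenceSet([s for s in self._sequences if s.id in wanted])

    def __repr__(self) -> str:
        return f"SequenceSet(n={len(self)})"


class AlignmentMatrix:
    """A rectangular gapped-sequence array, as produced by an MSA run."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        ids = list(ids)
        rows = list(rows)
        if len(ids) != len(rows):
            raise ContractError("ids and rows differ in length")
        if not rows:
            raise FormatError("alignment has no rows")
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise FormatError("alignment rows are empty")
        self.ids = ids
        self.rows = rows
        self._index = {i: k for k, i in enumerate(ids)}

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]]

    def degapped(self) -> SequenceSet:
        """Recover the unaligned input sequences, preserving row order."""
        return SequenceSet(
            [ProteinSequence(i, r.replace(GAP, "")) for i, r in zip(self.ids, self.rows)]
        )

    def reordered(self, ids: Sequence[str]) -> "AlignmentMatrix":
        """Rows permuted into the given id order."""
        return AlignmentMatrix(list(ids), [self.row(i) for i in ids])

    def __repr__(self) -> str:
        return f"AlignmentMatrix(n={len(self)}, L={self.length})"


class DistanceMatrix:
    """Symmetric matrix of ``dis = 1 - ID`` values over a sequence set."""

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        ids = list(ids)
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ContractError(f"values shape {values.shape} does not match {n} ids")
        if len(set(ids)) != len(ids):
            raise ContractError("duplicate ids in distance matrix")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ContractError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0.0):
            raise ContractError("distance matrix diagonal is not zero")
        if values.min() < -1e-12 or values.max() > 1.0 + 1e-12:
            raise ContractError("distance values outside [0, 1]")
        # exact symmetry + clipped range, so downstream equality tests are clean
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(values, 0.0)
        self.ids = ids
        self.values = values
        self._index = {i: k for k, i in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values in row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={len(self)})"


@dataclass
class LabeledDataset:
    """Sequences plus an id → family mapping; the benchmark's sample/label view."""

    sequences: SequenceSet
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = dict(self.labels)
        # fall back to the per-sequence family annotation when no map is given
        if not labels:
            labels = {s.id: s.family for s in self.sequences if s.family is not None}
        missing = [s.id for s in self.sequences if s.id not in labels]
        if missing:
            raise ContractError(f"no family label for sequence(s): {missing[:5]}")
        self.labels = {s.id: labels[s.id] for s in self.sequences}

    @property
    def families(self) -> list[str]:
        """Distinct family labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sequences:
            seen.setdefault(self.labels[s.id], None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        sub = self.sequences.subset(ids)
        return LabeledDataset(sub, {i: self.labels[i] for i in sub.ids})
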