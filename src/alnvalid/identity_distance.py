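"""Percent identity (ID) and the dis = 1 - ID distance.

ID is the number of matched residues divided by the whole aligned length.
For pairwise projections out of an MSA the denominator is governed by a
gap-column policy:

``keep-all`` (default)
    Every alignment column counts toward the length, including columns where
    both sequences have a gap. This is the literal reading of "whole length
    of aligned sequences" and explains why an MSA can assign identity < 1 to
    a pair of identical sequences.
``drop-dual-gap``
    Columns gapped in both sequences are removed before counting — the
    common convention for pairwise identity projected from an MSA.

A column pairing a residue with a gap counts toward the length but never
toward the match count, under both policies; gap-gap columns never match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GAP, AlignmentMatrix, DistanceMatrix
from .errors import ContractError, DegenerateInputError

GAP_POLICIES = ("keep-all", "drop-dual-gap")


@dataclass(frozen=True)
class IdentityScore:
    """Match count, denominator length, and their ratio for one pair."""

    matched: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1 or not (0 <= self.matched <= self.length):
            raise ContractError(
                f"invalid identity score: matched={self.matched}, length={self.length}"
            )

    @property
    def id_value(self) -> float:
        return self.matched / self.length


def _check_policy(policy: str) -> None:
    if policy not in GAP_POLICIES:
        raise ContractError(f"gap policy must be one of {GAP_POLICIES}, got {policy!r}")


def pairwise_identity(gapped_a: str, gapped_b: str, policy: str = "keep-all") -> IdentityScore:
    """ID of two equal-length gapped strings under the given gap-column policy."""
    _check_policy(policy)
    if len(gapped_a) != len(gapped_b):
        raise ContractError(
            f"gapped strings differ in length: {len(gapped_a)} vs {len(gapped_b)}"
        )
    if not gapped_a:
        raise ContractError("empty alignment")
    matched = 0
    dual_gaps = 0
    for x, y in zip(gapped_a, gapped_b):
        if x == GAP and y == GAP:
            dual_gaps += 1
        elif x == y and x != GAP:
            matched += 1
    length = len(gapped_a)
    if policy == "drop-dual-gap":
        length -= dual_gaps
        if length == 0:
            raise DegenerateInputError(
                "all columns are gap-gap; identity undefined under drop-dual-gap"
            )
    return IdentityScore(matched, length)


def identity_to_distance(id_value: float) -> float:
    """dis = 1 - ID, on [0, 1]."""
    if not 0.0 <= id_value <= 1.0:
        raise ContractError(f"identity must be in [0, 1], got {id_value}")
    return 1.0 - id_value


def msa_distance_matrix(m: AlignmentMatrix, policy: str = "keep-all") -> DistanceMatrix:
    """Pairwise dis matrix projected from the rows of an MSA.

    Entry (i, j) is ``1 - ID(row_i, row_j)`` under *policy*; the diagonal is
    forced to 0 (an MSA can report < 1 identity even for a row against an
    identical row, but a sequence is at distance 0 from itself by
    definition).
    """
    _check_policy(policy)
    if len(m) < 2:
        raise ContractError(f"need at least 2 rows, got {len(m)}")
    # byte matrix lets the O(n^2) pair loop run at numpy speed per pair
    R = np.frombuffer("".join(m.rows).encode("ascii"), dtype=np.uint8).reshape(
        len(m), m.length
    )
    gap = ord(GAP)
    n = len(m)
    values = np.zeros((n, n))
    for i in range(n):
        eq = R[i] == R[i + 1 :]
        nongap_i = R[i] != gap
        for k, j in enumerate(range(i + 1, n)):
            matched = int(np.count_nonzero(eq[k] & nongap_i))
            length = m.length
            if policy == "drop-dual-gap":
                dual = int(np.count_nonzero((R[i] == gap) & (R[j] == gap)))
                length -= dual
                if length == 0:
                    raise DegenerateInputError(
                        f"rows {m.ids[i]!r} and {m.ids[j]!r} share only gap-gap columns"
                    )
            values[i, j] = values[j, i] = 1.0 - matched / length
    return DistanceMatrix(list(m.ids), values)
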