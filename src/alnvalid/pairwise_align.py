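"""Global pairwise alignment (Needleman-Wunsch / Gotoh) and all-pairs distances.

This is the PSA route of the benchmark: every unordered pair of sequences is
globally aligned with affine (Gotoh) or linear gap penalties under a protein
substitution matrix, percent identity is read off the traceback, and
``dis = 1 - ID`` fills a :class:`DistanceMatrix`.

The dynamic program maximizes the summed substitution score minus gap
penalties over all global alignments, with end gaps penalized. Traceback
ties are broken deterministically: diagonal (match state) over up (gap in
the second sequence) over left (gap in the first). The identity of a pair
depends on which optimal traceback is taken, so this determinism is part of
the module contract, not an implementation detail.

The DP kernel is compiled with numba when available and falls back to the
identical pure-Python code otherwise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio.Align import substitution_matrices

from .containers import GAP, DistanceMatrix, ProteinSequence, SequenceSet
from .errors import ContractError, ScoringError
from .identity_distance import identity_to_distance, pairwise_identity

try:  # pragma: no cover - exercised implicitly by every alignment test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


#: Residues scored 0 against everything when the matrix lacks a row for them.
NEUTRAL_RESIDUES = frozenset("XBZU")

MODES = ("affine", "linear")

_NEG = -1.0e30


@dataclass(frozen=True)
class ScoreParams:
    """Scoring scheme for global alignment.

    ``gap_open`` is the cost of the first residue of a gap run and
    ``gap_extend`` the cost of each further residue, so a run of length k
    costs ``gap_open + (k-1)*gap_extend``. In ``linear`` mode every gap
    residue costs ``gap_open`` and ``gap_extend`` is ignored.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    mode: str = "affine"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ContractError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "affine":
            if not (self.gap_open <= self.gap_extend <= 0):
                raise ContractError(
                    f"affine mode requires gap_open <= gap_extend <= 0, "
                    f"got open={self.gap_open}, extend={self.gap_extend}"
                )
        elif self.gap_open > 0:
            raise ContractError(f"linear gap penalty must be <= 0, got {self.gap_open}")

    @property
    def effective_extend(self) -> float:
        return self.gap_open if self.mode == "linear" else self.gap_extend


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped strings of equal length plus the DP score."""

    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b) or not self.gapped_a:
            raise ContractError("gapped strings must have equal positive length")
        if any(x == GAP and y == GAP for x, y in zip(self.gapped_a, self.gapped_b)):
            raise ContractError("alignment contains a gap-gap column")

    @property
    def length(self) -> int:
        return len(self.gapped_a)

    def identity(self) -> float:
        """Percent identity of this alignment (matched residues / aligned length)."""
        return pairwise_identity(self.gapped_a, self.gapped_b).id_value


@functools.lru_cache(maxsize=8)
def _score_table(matrix_name: str) -> tuple[np.ndarray, frozenset]:
    """26x26 (A..Z indexed) score table plus the set of letters it covers.

    Letters absent from the matrix but in :data:`NEUTRAL_RESIDUES` score 0
    against everything; any other absent letter is a scoring error at encode
    time.
    """
    mat = substitution_matrices.load(matrix_name)
    alpha = [c for c in mat.alphabet if c.isalpha()]
    table = np.zeros((26, 26), dtype=np.float64)
    covered = set(alpha) | NEUTRAL_RESIDUES
    for x in alpha:
        for y in alpha:
            table[ord(x) - 65, ord(y) - 65] = mat[x, y]
    return table, frozenset(covered)


def available_matrices() -> list[str]:
    return sorted(substitution_matrices.load())


def _encode(seq: ProteinSequence, covered: frozenset) -> np.ndarray:
    bad = sorted(set(seq.residues) - covered)
    if bad:
        raise ScoringError(
            f"sequence {seq.id!r}: residue(s) {bad} have no substitution-matrix entry"
        )
    return np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8).astype(np.int64) - 65


@njit(cache=False)
def _gotoh_kernel(a, b, table, gap_open, gap_extend):  # pragma: no cover - jitted
    """Affine-gap global DP. Returns (score, ptr_m, ptr_x, ptr_y, end_state).

    States: 0 = M (a[i-1] ~ b[j-1]), 1 = X (a[i-1] ~ gap, "up"),
    2 = Y (gap ~ b[j-1], "left"). Pointers store the predecessor state.
    Tie-break everywhere prefers M, then X, then Y.
    """
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    pm = np.zeros((n + 1, m + 1), dtype=np.int8)
    px = np.zeros((n + 1, m + 1), dtype=np.int8)
    py = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        px[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        py[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # M: best predecessor at (i-1, j-1), prefer M > X > Y
            best = M[i - 1, j - 1]
            state = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                state = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                state = 2
            M[i, j] = best + table[ai, b[j - 1]]
            pm[i, j] = state
            # X: gap in b, predecessor at (i-1, j)
            best = M[i - 1, j] + gap_open
            state = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                state = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                state = 2
            X[i, j] = best
            px[i, j] = state
            # Y: gap in a, predecessor at (i, j-1)
            best = M[i, j - 1] + gap_open
            state = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                state = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                state = 2
            Y[i, j] = best
            py[i, j] = state
    score = M[n, m]
    end_state = 0
    if X[n, m] > score:
        score = X[n, m]
        end_state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        end_state = 2
    return score, pm, px, py, end_state


def nw_align(a: ProteinSequence, b: ProteinSequence, params: ScoreParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment of *a* and *b* under *params*.

    The returned score is the maximum over all global alignments; the
    traceback is the deterministic diagonal > up > left choice among
    optimal paths.
    """
    params = params or ScoreParams()
    if not a.residues or not b.residues:
        raise ContractError("cannot align empty sequences")
    table, covered = _score_table(params.matrix_name)
    ea = _encode(a, covered)
    eb = _encode(b, covered)
    score, pm, px, py, state = _gotoh_kernel(
        ea, eb, table, float(params.gap_open), float(params.effective_extend)
    )
    ptr = (pm, px, py)
    i, j = len(ea), len(eb)
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        prev = int(ptr[state][i, j])
        if state == 0:
            cols_a.append(a.residues[i - 1])
            cols_b.append(b.residues[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            cols_a.append(a.residues[i - 1])
            cols_b.append(GAP)
            i -= 1
        else:
            cols_a.append(GAP)
            cols_b.append(b.residues[j - 1])
            j -= 1
        state = prev
    return PairwiseAlignment("".join(reversed(cols_a)), "".join(reversed(cols_b)), float(score))


def all_pairs_distances(s: SequenceSet | Iterable[ProteinSequence], params: ScoreParams | None = None) -> DistanceMatrix:
    """Percent-identity distance matrix from all-pairs global alignment.

    Each unordered pair is aligned once; ``dis(i, j) = 1 - ID(i, j)`` with
    the diagonal exactly 0. Scoring failures are re-raised with the
    offending pair named.
    """
    params = params or ScoreParams()
    seqs = list(s)
    if len(seqs) < 2:
        raise ContractError(f"need at least 2 sequences, got {len(seqs)}")
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                aln = nw_align(seqs[i], seqs[j], params)
            except ScoringError as e:
                raise ScoringError(
                    f"pair ({seqs[i].id!r}, {seqs[j].id!r}): {e}"
                ) from e
            values[i, j] = values[j, i] = identity_to_distance(aln.identity())
    return DistanceMatrix([q.id for q in seqs], values)
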