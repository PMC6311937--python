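"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive enumeration and double
loops — and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def enumerate_global_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b).

    A global alignment consumes both strings left to right; each column is a
    substitution, a gap in b, or a gap in a. No gap-gap columns exist.
    """
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def best_alignment_score_linear(a: str, b: str, score: dict, gap: float) -> float:
    """Max alignment score by scoring every enumerated alignment: each
    residue pair scores ``score[(x, y)]``, each gapped column scores *gap*."""
    best = -np.inf
    for ga, gb in enumerate_global_alignments(a, b):
        total = 0.0
        for x, y in zip(ga, gb):
            total += gap if "-" in (x, y) else score[(x, y)]
        best = max(best, total)
    return best


def naive_silhouettes(d: np.ndarray, labels: list) -> np.ndarray:
    """Double-loop silhouette values: a(i) over own cluster excluding self,
    b(i) the minimum mean distance to any other cluster, singleton -> 0."""
    n = d.shape[0]
    out = np.zeros(n)
    clusters = sorted(set(labels), key=str)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = sum(d[i, j] for j in own) / len(own)
        b = np.inf
        for c in clusters:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(d[i, j] for j in members) / len(members))
        m = max(a, b)
        out[i] = 0.0 if m == 0 else (b - a) / m
    return out


def naive_rs(d: np.ndarray, labels: list) -> float:
    """Pair-loop RS with per-cluster within centers and a global mean."""
    n = d.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    x = np.array([d[i, j] for i, j in pairs])
    xbar = x.mean()
    ss_t = ((x - xbar) ** 2).sum()
    if ss_t == 0:
        return 0.0
    ss_w = 0.0
    for c in sorted(set(labels), key=str):
        xw = np.array([d[i, j] for i, j in pairs if labels[i] == labels[j] == c])
        if len(xw):
            ss_w += ((xw - xw.mean()) ** 2).sum()
    return (ss_t - ss_w) / ss_t


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix in [0, 1] with zero diagonal."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
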