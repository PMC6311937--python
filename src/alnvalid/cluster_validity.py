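"""Silhouette-width (SW) and RS cluster-validity scores on a distance matrix.

Both scores are computed directly from a distance matrix plus known family
labels — no clustering algorithm is run. This is the evaluation core of the
benchmark: an alignment method is judged by how well the distances it
induces separate the known families.

Silhouette of sequence i:

    S(i) = (b(i) - a(i)) / max{a(i), b(i)}

with a(i) the mean distance from i to the *other* members of its own family
and b(i) the smallest mean distance from i to any other family. SW is the
arithmetic mean of the S(i) and lies in [-1, 1]. A member of a singleton
family gets S(i) = 0 (the standard convention; resampling can strand a
family with one member). If a(i) = b(i) = 0 the silhouette is 0.

RS index:

    RS = (SS_t - SS_w) / SS_t

where the "samples" are the pairwise distances themselves: SS_t is the sum
of squared deviations of all n(n-1)/2 pairwise distances from their global
mean, and SS_w sums, per family, the squared deviations of within-family
distances from that family's mean within-distance. With per-family centers
SS_w <= SS_t, so RS lies in [0, 1]. An alternative centering of SS_w about
the global mean is available via ``ss_w_center="global"``. If SS_t = 0
(all distances equal) there is no separable structure and RS is defined
as 0.

Both scores are ratios, so shrinking all distances by a common factor —
which a PSA does relative to an MSA — leaves them unchanged; the comparison
between alignment methods is driven only by the contrast between
within-family and between-family distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .containers import DistanceMatrix
from .errors import ContractError

SS_W_CENTERS = ("cluster", "global")


@dataclass(frozen=True)
class ValidityResult:
    """Per-sequence silhouettes plus the SW / RS summary for one dataset."""

    ids: tuple[str, ...]
    silhouettes: np.ndarray
    sw: float
    rs: float
    n: int
    ss_t: float
    ss_w: float


def _label_array(d: DistanceMatrix, labels: Mapping[str, str]) -> tuple[np.ndarray, list[str]]:
    missing = [i for i in d.ids if i not in labels]
    if missing:
        raise ContractError(f"label missing for id(s): {missing[:5]}")
    fams: list[str] = []
    index: dict[str, int] = {}
    y = np.empty(len(d.ids), dtype=np.int64)
    for k, sid in enumerate(d.ids):
        fam = labels[sid]
        if fam not in index:
            index[fam] = len(fams)
            fams.append(fam)
        y[k] = index[fam]
    if len(fams) < 2:
        raise ContractError(
            f"validity scores need >= 2 distinct families, got {len(fams)}"
        )
    return y, fams


def silhouette_values(d: DistanceMatrix, labels: Mapping[str, str]) -> np.ndarray:
    """S(i) for every sequence, in the matrix's id order."""
    y, fams = _label_array(d, labels)
    k = len(fams)
    onehot = np.zeros((len(y), k))
    onehot[np.arange(len(y)), y] = 1.0
    counts = onehot.sum(axis=0)  # members per family
    sums = d.values @ onehot  # (n, k) summed distance from i to each family
    own = counts[y]
    s = np.zeros(len(y))
    multi = own > 1  # singleton families keep S(i) = 0
    a = np.zeros(len(y))
    a[multi] = sums[multi, y[multi]] / (own[multi] - 1)
    mean_to = sums / counts  # (n, k) mean distance from i to each family
    mean_to[np.arange(len(y)), y] = np.inf  # exclude own family from b(i)
    b = mean_to.min(axis=1)
    denom = np.maximum(a, b)
    ok = multi & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return s


def sw_score(d: DistanceMatrix, labels: Mapping[str, str]) -> float:
    """Mean silhouette SW, in [-1, 1]."""
    return float(silhouette_values(d, labels).mean())


def _rs_sums(
    d: DistanceMatrix, labels: Mapping[str, str], ss_w_center: str
) -> tuple[float, float]:
    if ss_w_center not in SS_W_CENTERS:
        raise ContractError(f"ss_w_center must be one of {SS_W_CENTERS}")
    y, _ = _label_array(d, labels)
    iu, ju = np.triu_indices(len(y), k=1)
    x = d.values[iu, ju]  # all pairwise distances
    within = y[iu] == y[ju]
    if not within.any():
        raise ContractError("no within-family pair exists; RS is undefined")
    xbar = x.mean()
    ss_t = float(((x - xbar) ** 2).sum())
    ss_w = 0.0
    for fam in np.unique(y[iu][within]):
        xw = x[within & (y[iu] == fam)]
        center = xw.mean() if ss_w_center == "cluster" else xbar
        ss_w += float(((xw - center) ** 2).sum())
    return ss_t, ss_w


def rs_score(
    d: DistanceMatrix, labels: Mapping[str, str], ss_w_center: str = "cluster"
) -> float:
    """RS = (SS_t - SS_w) / SS_t over pairwise distances; 0 when SS_t = 0."""
    ss_t, ss_w = _rs_sums(d, labels, ss_w_center)
    if ss_t == 0.0:
        return 0.0
    rs = (ss_t - ss_w) / ss_t
    # guard rounding at the boundaries; mathematically 0 <= SS_w <= SS_t
    # under cluster centering (global centering can only lower RS further)
    return float(min(max(rs, 0.0), 1.0))


def evaluate(
    d: DistanceMatrix, labels: Mapping[str, str], ss_w_center: str = "cluster"
) -> ValidityResult:
    """Silhouettes, SW and RS for one (distance matrix, labels) pair."""
    s = silhouette_values(d, labels)
    ss_t, ss_w = _rs_sums(d, labels, ss_w_center)
    rs = 0.0 if ss_t == 0.0 else float(min(max((ss_t - ss_w) / ss_t, 0.0), 1.0))
    return ValidityResult(
        ids=tuple(d.ids),
        silhouettes=s,
        sw=float(s.mean()),
        rs=rs,
        n=len(d.ids),
        ss_t=ss_t,
        ss_w=ss_w,
    )
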