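"""Pairwise global alignment and uncorrected genetic distance.

Both tiers of the OTU framework (clade binning at 0.15 and species/type
OTUs at 0.03) operate on uncorrected p-distances: the fraction of
differing positions between two globally aligned sequences, with each
maximal internal gap run optionally compressed to a single difference
and terminal gaps ignored.  Alignment is Needleman–Wunsch with affine
gap penalties (Gotoh's algorithm) and deterministic traceback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentParams",
    "GapPolicy",
    "DistanceMatrix",
    "global_align",
    "align_score",
    "uncorrected_distance",
    "pairwise_distance",
    "distance_matrix",
]

GAP = "-"
_NEG_INF = -1e18


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring for global alignment.

    A gap of length ``k`` costs ``gap_open + (k - 1) * gap_extend``.
    """

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be below match score")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


@dataclass(frozen=True)
class GapPolicy:
    """How gap columns enter the distance.

    ``gap_run_counts_as='one'`` compresses each maximal internal gap run
    to a single difference over a single comparable position (the default
    of the distance calculator in common amplicon toolkits); ``'each'``
    counts every gap column separately.  Terminal gap columns are
    excluded when ``ignore_terminal_gaps`` is true.
    """

    gap_run_counts_as: Literal["one", "each"] = "one"
    ignore_terminal_gaps: bool = True

    def __post_init__(self) -> None:
        if self.gap_run_counts_as not in ("one", "each"):
            raise ValueError("gap_run_counts_as must be 'one' or 'each'")


def _fill_numpy(av, bv, match, mismatch, go, ge):
    """Row-vectorised Gotoh fill (fallback when numba is unavailable)."""
    n, m = len(av), len(bv)
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    j_idx = np.arange(1, m + 1)
    Y[0, 1:] = go + ge * (j_idx - 1)

    sub_row = np.where(bv[None, :] == av[:, None], match, mismatch)
    ge_ramp = ge * np.arange(m + 1)

    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = best_prev[:-1] + sub_row[i - 1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) + go, X[i - 1, 1:] + ge
        )
        # Y[i, j] = max_{k<j} (max(M, X)[i, k] + go + ge*(j-1-k)); prefix-max trick
        z = np.maximum(M[i], X[i]) - ge_ramp
        running = np.maximum.accumulate(z[:-1])
        Y[i, 1:] = running + go + ge_ramp[1:] - ge
    return M, X, Y


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _fill_numba(av, bv, match, mismatch, go, ge):  # pragma: no cover
        n, m = len(av), len(bv)
        M = np.full((n + 1, m + 1), _NEG_INF)
        X = np.full((n + 1, m + 1), _NEG_INF)
        Y = np.full((n + 1, m + 1), _NEG_INF)
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            X[i, 0] = go + ge * (i - 1)
        for j in range(1, m + 1):
            Y[0, j] = go + ge * (j - 1)
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                s = match if av[i - 1] == bv[j - 1] else mismatch
                prev = M[i - 1, j - 1]
                if X[i - 1, j - 1] > prev:
                    prev = X[i - 1, j - 1]
                if Y[i - 1, j - 1] > prev:
                    prev = Y[i - 1, j - 1]
                M[i, j] = prev + s
                x = M[i - 1, j] + go
                if X[i - 1, j] + ge > x:
                    x = X[i - 1, j] + ge
                if Y[i - 1, j] + go > x:
                    x = Y[i - 1, j] + go
                X[i, j] = x
                y = M[i, j - 1] + go
                if Y[i, j - 1] + ge > y:
                    y = Y[i, j - 1] + ge
                if X[i, j - 1] + go > y:
                    y = X[i, j - 1] + go
                Y[i, j] = y
        return M, X, Y

    _FILL = _fill_numba
except ImportError:  # pragma: no cover
    _FILL = _fill_numpy


def _dp_matrices(a: str, b: str, p: AlignmentParams):
    """Fill the three Gotoh score matrices.

    M: a[i-1] aligned to b[j-1]; X: gap in b (consumes a, "up" move);
    Y: gap in a (consumes b, "left" move).
    """
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return _FILL(av, bv, float(p.match), float(p.mismatch),
                 float(p.gap_open), float(p.gap_extend))


def align_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global alignment score under affine gap penalties."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    p = params or AlignmentParams()
    M, X, Y = _dp_matrices(a, b, p)
    return float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))


def global_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[str, str]:
    """Globally align two sequences; returns equal-length gapped strings.

    Traceback ties are broken deterministically: diagonal (match state),
    then up (gap in the second sequence), then left.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    p = params or AlignmentParams()
    M, X, Y = _dp_matrices(a, b, p)
    go, ge = p.gap_open, p.gap_extend

    i, j = len(a), len(b)
    finals = (M[i, j], X[i, j], Y[i, j])
    state = int(np.argmax(finals))  # argmax takes first on ties: M > X > Y

    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: consume a[i-1], b[j-1]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev)) if (i, j) != (0, 0) else 0
        elif state == 1:  # X: consume a[i-1], gap in b
            out_a.append(a[i - 1])
            out_b.append(GAP)
            target = X[i, j]
            # which predecessor produced this score? prefer M, then X, then Y
            if abs(M[i - 1, j] + go - target) < 1e-6:
                state = 0
            elif abs(X[i - 1, j] + ge - target) < 1e-6:
                state = 1
            else:
                state = 2
            i -= 1
        else:  # Y: gap in a, consume b[j-1]
            out_a.append(GAP)
            out_b.append(b[j - 1])
            target = Y[i, j]
            if abs(M[i, j - 1] + go - target) < 1e-6:
                state = 0
            elif abs(Y[i, j - 1] + ge - target) < 1e-6:
                state = 2
            else:
                state = 1
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def uncorrected_distance(
    aligned_a: str, aligned_b: str, policy: GapPolicy | None = None
) -> float:
    """Uncorrected p-distance between two aligned sequences.

    Mismatched base columns contribute one difference over one position;
    matched columns one position.  Under the default policy each maximal
    internal gap run contributes one difference over one position, and
    terminal gap columns are excluded entirely.

    Raises
    ------
    ValueError
        If the aligned strings differ in length or no comparable
        positions remain.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    pol = policy or GapPolicy()
    L = len(aligned_a)
    start, end = 0, L
    if pol.ignore_terminal_gaps:
        while start < L and (aligned_a[start] == GAP or aligned_b[start] == GAP):
            start += 1
        while end > start and (aligned_a[end - 1] == GAP or aligned_b[end - 1] == GAP):
            end -= 1

    diffs = 0
    positions = 0
    in_gap_a = in_gap_b = False
    for k in range(start, end):
        ca, cb = aligned_a[k], aligned_b[k]
        if ca == GAP or cb == GAP:
            if pol.gap_run_counts_as == "each":
                diffs += 1
                positions += 1
            else:
                gap_in_a = ca == GAP
                new_run = not (in_gap_a if gap_in_a else in_gap_b)
                if new_run:
                    diffs += 1
                    positions += 1
            in_gap_a, in_gap_b = ca == GAP, cb == GAP
        else:
            positions += 1
            if ca != cb:
                diffs += 1
            in_gap_a = in_gap_b = False
    if positions == 0:
        raise ValueError("no comparable positions between aligned sequences")
    return diffs / positions


def pairwise_distance(
    a: str,
    b: str,
    params: AlignmentParams | None = None,
    policy: GapPolicy | None = None,
) -> float:
    """Align two unaligned sequences and return their uncorrected distance.

    The pair is canonicalised (lexicographically ordered) before
    alignment so the result is strictly symmetric even when several
    optimal alignments exist.
    """
    if a == b:
        return 0.0
    if b < a:
        a, b = b, a
    p = params or AlignmentParams()
    if len(a) == len(b):
        # Fast path: for equal lengths with few substitutions the gap-free
        # alignment is provably optimal.  Any alignment with g >= 1 gap
        # columns per sequence scores at most
        # (L-g)*match + 2*(gap_open + (g-1)*gap_extend), which beats the
        # identity alignment (L-k)*match + k*mismatch only when
        # k*(match-mismatch) > match - 2*gap_open.
        k = sum(x != y for x, y in zip(a, b))
        if k * (p.match - p.mismatch) <= p.match - 2 * p.gap_open:
            return k / len(a)
    aa, ab = global_align(a, b, p)
    return uncorrected_distance(aa, ab, policy)


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected-distance matrix over labelled variants."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("distances must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_square_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", index_label="id", lineterminator="\n")

    def to_sparse_tsv(self, path: str | Path) -> None:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.labels[i], self.labels[j], self.values[i, j]))
        pd.DataFrame(rows, columns=["id1", "id2", "dist"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


def distance_matrix(
    sequences: Sequence[str],
    labels: Sequence[str] | None = None,
    params: AlignmentParams | None = None,
    policy: GapPolicy | None = None,
) -> DistanceMatrix:
    """All-pairs uncorrected distances for a set of unaligned sequences."""
    if len(sequences) < 1:
        raise ValueError("need at least one sequence")
    if labels is None:
        labels = [str(i) for i in range(len(sequences))]
    if len(labels) != len(sequences):
        raise ValueError("labels/sequences length mismatch")
    n = len(sequences)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(sequences[i], sequences[j], params, policy)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(list(labels), vals)
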