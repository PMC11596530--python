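"""Pairwise semi-global DNA alignment and p-distance.

This is the distance kernel used to resolve "unique" ASVs to their most
similar source sequence.  The alignment is semi-global (terminal gaps are
free): amplicon variants may differ in trimmed length, and penalising
terminal overhangs would inflate the distance between biologically identical
variants.  The dynamic program fills one row at a time with numpy; the
traceback is deterministic (tie order diagonal > up > left, and the
end-point preference is fixed), so outputs are reproducible bit for bit.

p-distance is the proportion of mismatching base–base columns: gap columns
and columns containing an ambiguous (non-ACGT) code are excluded from the
denominator.  An alignment with zero comparable columns has no defined
distance and raises instead of returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IUPAC_CODES

__all__ = ["Scoring", "PairwiseAlignment", "PDistance", "global_align", "p_distance"]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class Scoring:
    """Linear (non-affine) alignment scoring scheme."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A pairwise alignment: two equal-length gapped strings and the score.

    Removing the gaps from ``aligned_a``/``aligned_b`` recovers the input
    sequences exactly; no column is gap–gap.
    """

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap-gap column in alignment")


@dataclass(frozen=True)
class PDistance:
    """p-distance: mismatching base–base columns / comparable columns."""

    value: float
    n_compared_columns: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"p-distance out of range: {self.value}")
        if self.n_compared_columns <= 0:
            raise ValueError("p-distance undefined with no compared columns")


def _validate_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"empty sequence {name}")
    bad = next((i for i, c in enumerate(seq) if c not in IUPAC_CODES), None)
    if bad is not None:
        raise ValueError(f"non-IUPAC character {seq[bad]!r} at position {bad} in {name}")


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal semi-global alignment of two DNA sequences.

    Terminal gaps score zero; internal gaps cost ``scoring.gap`` per base
    (linear).  Ambiguity codes are scored as mismatches against everything
    (they are excluded from p-distance anyway).

    The traceback is canonicalised to the lexicographic order of the inputs,
    so ``global_align(a, b)`` and ``global_align(b, a)`` return mirror-image
    alignments even when several alignments share the optimal score.
    """
    _validate_sequence(a, "a")
    _validate_sequence(b, "b")
    if b < a:
        aln = global_align(b, a, scoring)
        return PairwiseAlignment(aln.aligned_b, aln.aligned_a, aln.score)
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    # ambiguity codes never "match": remap every non-ACGT byte in a to a
    # sentinel that cannot equal any byte of b
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    av = np.where(np.isin(av, acgt), av, np.uint8(0))
    bv = np.where(np.isin(bv, acgt), bv, np.uint8(1))

    g = float(scoring.gap)
    H = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    jj = np.arange(m + 1)
    t = np.empty(m + 1)
    for i in range(1, n + 1):
        s = np.where(av[i - 1] == bv, scoring.match, scoring.mismatch)
        diag = H[i - 1, :-1] + s
        up = H[i - 1, 1:] + g
        cand = np.maximum(diag, up)
        # left moves within the row: H[i,j] = g*j + max_{k<=j}(cand_k - g*k),
        # with k=0 standing for the free-leading-gap cell H[i,0] = 0
        t[0] = 0.0
        t[1:] = cand - g * jj[1:]
        H[i] = g * jj + np.maximum.accumulate(t)
        H[i, 0] = 0.0
        row = H[i, 1:]
        ptr[i, 1:] = np.where(row == diag, 0, np.where(row == up, 1, 2))

    # free trailing gaps: best score over last row and last column; prefer the
    # last row, and within it the rightmost maximum (ties resolved fixed)
    j_best = m - int(np.argmax(H[n, ::-1]))
    i_best = n - int(np.argmax(H[::-1, m]))
    if H[n, j_best] >= H[i_best, m]:
        ei, ej = n, j_best
    else:
        ei, ej = i_best, m
    score = float(H[ei, ej])

    core_a: list[str] = []
    core_b: list[str] = []
    i, j = ei, ej
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 0:
            core_a.append(a[i - 1])
            core_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            core_a.append(a[i - 1])
            core_b.append("-")
            i -= 1
        else:
            core_a.append("-")
            core_b.append(b[j - 1])
            j -= 1
    aligned_a = a[:i] + "-" * j + "".join(reversed(core_a)) + a[ei:] + "-" * (m - ej)
    aligned_b = "-" * i + b[:j] + "".join(reversed(core_b)) + "-" * (n - ei) + b[ej:]
    return PairwiseAlignment(aligned_a, aligned_b, score)


def p_distance(aln: PairwiseAlignment) -> PDistance:
    """p-distance of an alignment over its base–base (ACGT vs ACGT) columns."""
    compared = 0
    mismatches = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x in _ACGT and y in _ACGT:
            compared += 1
            if x != y:
                mismatches += 1
    if compared == 0:
        raise ValueError("no overlap: alignment has no comparable base-base columns")
    return PDistance(mismatches / compared, compared)
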