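"""Inverted-repeat discovery by self-reverse-complement local alignment.

Two nearby segments that are reverse complements of one another are the
classic signature of a replication origin on small circular chromosomes.
The detector here follows the einverted-style scheme: a Smith-Waterman
local alignment of the sequence against its own reverse complement, with
a linear per-position gap penalty, constrained so that the two aligned
segments (the repeat arms) are disjoint and ordered on the chosen
linearization.

Default scoring: match +3, mismatch -4, gap penalty 5 per gap position,
minimum reported score 15.  A perfect palindromic arm pair of arm length
``a`` therefore scores ``3a`` and becomes reportable at ``a >= 5``.

Circular sequences are searched on a doubled linearization; hits whose
first arm starts in the second copy are duplicates and are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .seq_core import Interval, NucSequence, reverse_complement

__all__ = ["IRScoringParams", "InvertedRepeatHit", "find_inverted_repeats"]


@dataclass(frozen=True)
class IRScoringParams:
    match: int = 3
    mismatch: int = -4
    gap_penalty: int = 5  # subtracted per gap position
    min_score: int = 15
    min_arm: int = 3
    max_spacer: Optional[int] = None

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_penalty <= 0:
            raise ValueError("require match > 0, mismatch < 0, gap_penalty > 0")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


DEFAULT_IR_PARAMS = IRScoringParams()


@dataclass(frozen=True)
class InvertedRepeatHit:
    """Two disjoint arms whose sequences align as reverse complements.

    ``region_span`` is the distance from the start of arm 1 to the end of
    arm 2 (arms plus spacer), the figure usually quoted as the size of an
    inverted-repeat "region"; arm lengths are available from the
    intervals.
    """

    arm1: Interval
    arm2: Interval
    spacer_len: int
    score: int
    region_span: int


_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _complementary(x: str, y: str) -> bool:
    return (x, y) in _PAIR


def _fill_matrix(s: str, p: IRScoringParams) -> np.ndarray:
    """Local-alignment DP of ``s`` vs its reverse complement.

    Cell (i, j), 0-based, scores alignments ending with ``s[i]`` paired
    against reverse-complement position ``j`` (i.e. forward position
    ``n-1-j``).  Only the triangle ``i + j <= n - 2`` is valid: it forces
    arm 1 to end strictly before arm 2 starts, which also picks exactly
    one of the two mirror-image representations of every repeat.
    """
    n = len(s)
    g = p.gap_penalty
    r = reverse_complement(s)
    es = np.frombuffer(s.encode(), dtype=np.uint8)
    er = np.frombuffer(r.encode(), dtype=np.uint8)
    H = np.zeros((n, n), dtype=np.int32)
    idx = np.arange(n, dtype=np.int32)
    prev = np.zeros(n, dtype=np.int32)
    for i in range(n):
        limit = n - 1 - i  # valid columns are j < limit
        if limit <= 0:
            break
        sub = np.where(er == es[i], p.match, p.mismatch).astype(np.int32)
        diag = np.empty(n, dtype=np.int32)
        diag[0] = 0
        diag[1:] = prev[:-1]
        A = np.maximum(0, np.maximum(diag + sub, prev - g))
        A[limit:] = 0
        # unroll the within-row horizontal gap chain
        row = np.maximum.accumulate(A + g * idx) - g * idx
        row = np.maximum(row, 0)
        row[limit:] = 0
        H[i] = row
        prev = row
    return H


def _traceback(s: str, H: np.ndarray, i: int, j: int, g: int, p: IRScoringParams):
    """Walk back from (i, j) to the start of the local path."""
    n = len(s)
    i1, j1 = i, j
    while True:
        val = H[i, j]
        if val <= 0:
            break
        x = s[i]
        y = s[n - 1 - j]
        diag = H[i - 1, j - 1] if i > 0 and j > 0 else 0
        step = p.match if _complementary(x, y) else p.mismatch
        if diag + step == val:
            if i == 0 or j == 0:
                i0, j0 = i, j
                return i0, j0, i1, j1
            i, j = i - 1, j - 1
            if H[i, j] <= 0:
                return i + 1, j + 1, i1, j1
        elif i > 0 and H[i - 1, j] - g == val:
            i -= 1
        elif j > 0 and H[i, j - 1] - g == val:
            j -= 1
        else:
            # path starts here with a match from zero
            break
    return i, j, i1, j1


def _hit_from_cell(s: str, H: np.ndarray, i: int, j: int, p: IRScoringParams):
    n = len(s)
    i0, j0, i1, j1 = _traceback(s, H, i, j, p.gap_penalty, p)
    arm1_start, arm1_end = i0, i1 + 1
    arm2_start, arm2_end = n - 1 - j1, n - j0
    return (arm1_start, arm1_end, arm2_start, arm2_end, int(H[i1, j1]))


def find_inverted_repeats(
    seq: NucSequence | str, params: IRScoringParams = DEFAULT_IR_PARAMS
) -> list[InvertedRepeatHit]:
    """Report inverted repeats scoring at least ``params.min_score``.

    Hits are selected greedily by descending score (ties by arm-1 start,
    then region span); a candidate whose arms overlap an already accepted
    hit's arms is suppressed.  On circular input, coordinates are reported
    modulo the circle length and an arm crossing the origin is returned as
    a wrapping interval.
    """
    if isinstance(seq, str):
        seq = NucSequence("seq", seq)
    L = len(seq)
    if L < 2 * params.min_arm:
        warnings.warn(
            f"sequence {seq.id!r} shorter than two minimum arms; no search done"
        )
        return []
    s = seq.residues * 2 if seq.is_circular else seq.residues
    n = len(s)
    H = _fill_matrix(s, params)

    cand = np.argwhere(H >= params.min_score)
    if cand.size == 0:
        return []
    order = np.lexsort((cand[:, 1], cand[:, 0], -H[cand[:, 0], cand[:, 1]]))
    raw_hits = []
    seen = set()
    for k in order:
        i, j = int(cand[k, 0]), int(cand[k, 1])
        a1s, a1e, a2s, a2e, score = _hit_from_cell(s, H, i, j, params)
        if a1e - a1s < params.min_arm or a2e - a2s < params.min_arm:
            continue
        spacer = a2s - a1e
        if spacer < 0:
            continue
        if params.max_spacer is not None and spacer > params.max_spacer:
            continue
        if seq.is_circular:
            if a1s >= L:
                continue  # duplicate from the second copy
            if a2e - a1s > L:
                continue  # arms would overlap on the circle
        key = (a1s, a1e, a2s, a2e)
        if key in seen:
            continue
        seen.add(key)
        raw_hits.append((score, a1s, a1e, a2s, a2e, spacer))

    raw_hits.sort(key=lambda h: (-h[0], h[1], h[4] - h[1]))
    occupied = np.zeros(L, dtype=bool)
    hits: list[InvertedRepeatHit] = []
    for score, a1s, a1e, a2s, a2e, spacer in raw_hits:
        positions = [p % L for p in range(a1s, a1e)] + [
            p % L for p in range(a2s, a2e)
        ]
        if any(occupied[p] for p in positions):
            continue
        for p in positions:
            occupied[p] = True
        hits.append(
            InvertedRepeatHit(
                arm1=_normalize_interval(a1s, a1e, L, seq.is_circular),
                arm2=_normalize_interval(a2s, a2e, L, seq.is_circular),
                spacer_len=spacer,
                score=score,
                region_span=a2e - a1s,
            )
        )
    return hits


def _normalize_interval(start: int, end: int, L: int, circular: bool) -> Interval:
    """Map doubled-linearization coordinates back onto the circle."""
    if not circular:
        return Interval(start, end)
    if start >= L:
        start, end = start - L, end - L
    if end <= L:
        return Interval(start, end)
    return Interval(start, end - L, wraps=True)
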