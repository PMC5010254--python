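"""Deterministic pairwise alignment and reference-coordinate clone mapping.

Clone sequences from a single individual are near-identical (>98%), so
instead of a progressive multiple alignment each clone is aligned to the
reference circle independently and projected onto reference coordinates.
For site-calling this is equivalent to an MSA of near-identical sequences
while remaining exactly testable against a brute-force oracle.

The aligner is a standard affine-gap Needleman-Wunsch (Gotoh) with a
fixed traceback tie order (diagonal, then vertical, then horizontal) so
results are bit-reproducible.  A gap of length ``k`` scores
``gap_open + (k - 1) * gap_extend``.

Insertions relative to the reference do not create matrix columns: they
are stored as side records, because downstream site-calling counts
substitution columns and indel events separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .circle import Minicircle
from .seq_core import NucSequence, SequenceError

__all__ = [
    "AlignParams",
    "PairwiseAlignment",
    "InsertionRecord",
    "ColumnMatrix",
    "global_align",
    "semiglobal_align",
    "map_clones",
    "DEFAULT_PARAMS",
    "NONCODING_PARAMS",
]


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1


DEFAULT_PARAMS = AlignParams()
# permissive preset for diverged noncoding regions, where gap-heavy
# alignments are expected and identity is reported as exploratory only
NONCODING_PARAMS = AlignParams(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)

_NEG = -(10**8)

# symbol used in a ColumnMatrix for reference positions a clone does not cover,
# as distinct from '-' (covered but deleted)
UNCOVERED = "."


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gapped alignment of two sequences; removing gaps recovers the inputs."""

    aligned_a: str
    aligned_b: str
    score: int
    params: AlignParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("gap/gap column in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_matches(self) -> int:
        return sum(
            x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _gotoh(a: str, b: str, p: AlignParams, free_b_ends: bool):
    """Fill Gotoh matrices.  Returns (M, X, Y) of shape (n+1, m+1).

    State M ends in a substitution column, X in a gap in ``b`` (vertical,
    consumes ``a``), Y in a gap in ``a`` (horizontal, consumes ``b``).
    With ``free_b_ends`` the alignment may start at any position of ``b``
    at no cost (used for mapping a clone onto a long reference).
    """
    n, m = len(a), len(b)
    go, ge = p.gap_open, p.gap_extend
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    M[0, 0] = 0
    if n >= 1:
        X[1:, 0] = go + np.arange(n, dtype=np.int32) * ge
    if m >= 1:
        if free_b_ends:
            M[0, :] = 0
        else:
            Y[0, 1:] = go + np.arange(m, dtype=np.int32) * ge

    ea, eb = _encode(a), _encode(b)
    idx = np.arange(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(eb == ea[i - 1], p.match, p.mismatch).astype(np.int32)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        if free_b_ends:
            pass  # M[i,0] stays unreachable; restarts happen only on row 0
        X[i] = np.maximum(np.maximum(M[i - 1], Y[i - 1]) + go, X[i - 1] + ge)
        X[i, 0] = go + (i - 1) * ge
        # Y depends on M/X of the same row at earlier columns; unroll the
        # horizontal chain with a running maximum.
        B = np.maximum(M[i], X[i]) + go
        run = np.maximum.accumulate(B - idx * ge)
        Y[i, 1:] = run[:-1] + idx[:-1] * ge
        Y[i, 0] = _NEG
    return M, X, Y


def _traceback(a, b, p, M, X, Y, i, j, state, free_b_ends=False):
    """Deterministic traceback; returns (aligned_a, aligned_b, start_j)."""
    go, ge = p.gap_open, p.gap_extend
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if free_b_ends and i == 0:
            break
        if state == "M":
            if i == 0 or j == 0:
                break
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            want = M[i, j] - s
            if want == M[i - 1, j - 1]:
                state = "M"
            elif want == X[i - 1, j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            val = X[i, j]
            if val == M[i - 1, j] + go:
                state = "M"
            elif val == X[i - 1, j] + ge:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            cols_a.append("-")
            cols_b.append(b[j - 1])
            val = Y[i, j]
            if val == M[i, j - 1] + go:
                state = "M"
            elif val == Y[i, j - 1] + ge:
                state = "Y"
            else:
                state = "X"
            j -= 1
    return "".join(reversed(cols_a)), "".join(reversed(cols_b)), j


def global_align(
    a: NucSequence | str, b: NucSequence | str, params: AlignParams = DEFAULT_PARAMS
) -> PairwiseAlignment:
    """Optimal global alignment of two linear sequences under affine gaps."""
    sa = a.residues if isinstance(a, NucSequence) else a.upper()
    sb = b.residues if isinstance(b, NucSequence) else b.upper()
    if not sa or not sb:
        raise SequenceError("cannot align an empty sequence")
    M, X, Y = _gotoh(sa, sb, params, free_b_ends=False)
    n, m = len(sa), len(sb)
    finals = {"M": M[n, m], "X": X[n, m], "Y": Y[n, m]}
    state = max(("M", "X", "Y"), key=lambda k: (finals[k], k == "M", k == "X"))
    score = int(finals[state])
    aln_a, aln_b, _ = _traceback(sa, sb, params, M, X, Y, n, m, state)
    return PairwiseAlignment(aln_a, aln_b, score, params)


def semiglobal_align(
    query: NucSequence | str,
    reference: NucSequence | str,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[PairwiseAlignment, int]:
    """Align ``query`` end-to-end against the best-matching window of ``reference``.

    Reference bases before and after the aligned window cost nothing and
    are not part of the returned alignment.  Returns the alignment and the
    0-based reference offset of its first column.  Ties on score resolve
    to the leftmost window.
    """
    sq = query.residues if isinstance(query, NucSequence) else query.upper()
    sr = reference.residues if isinstance(reference, NucSequence) else reference.upper()
    if not sq or not sr:
        raise SequenceError("cannot align an empty sequence")
    M, X, Y = _gotoh(sq, sr, params, free_b_ends=True)
    n = len(sq)
    last = np.maximum(M[n], X[n])
    j_end = int(np.argmax(last))  # argmax takes the first (leftmost) maximum
    state = "M" if M[n, j_end] >= X[n, j_end] else "X"
    score = int(last[j_end])
    aln_q, aln_r, j_start = _traceback(
        sq, sr, params, M, X, Y, n, j_end, state, free_b_ends=True
    )
    return PairwiseAlignment(aln_q, aln_r, score, params), j_start


# ---------------------------------------------------------------------------
# Reference-coordinate clone matrix


@dataclass(frozen=True)
class InsertionRecord:
    """Bases present in a clone but absent from the reference.

    ``ref_pos`` is the reference position *before which* the inserted
    bases sit (0-based, on the circle).
    """

    ref_pos: int
    clone_id: str
    inserted: str


@dataclass
class ColumnMatrix:
    """Clone bases projected onto reference coordinates.

    One column per reference position.  Symbols are the clone base, '-'
    for a base deleted in the clone, or '.' for positions outside the
    region the clone covers.  Insertions are held separately in
    ``insertions``.
    """

    reference_id: str
    reference_residues: str
    clone_ids: list[str]
    rows: np.ndarray  # (n_clones, L) of single characters
    insertions: list[InsertionRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.reference_residues)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def column(self, pos: int) -> list[str]:
        return [str(x) for x in self.rows[:, pos]]

    def covered_by_all(self) -> np.ndarray:
        """Boolean mask of reference positions covered by every clone."""
        return np.all(self.rows != UNCOVERED, axis=0)

    def row_string(self, clone_idx: int) -> str:
        return "".join(self.rows[clone_idx])

    def insertions_for(self, clone_id: str) -> list[InsertionRecord]:
        return [r for r in self.insertions if r.clone_id == clone_id]


def map_clones(
    reference: Minicircle,
    clones: Sequence[NucSequence],
    params: AlignParams = DEFAULT_PARAMS,
    min_identity: float = 0.6,
) -> ColumnMatrix:
    """Map clone sequences onto a reference circle.

    Each clone is semiglobally aligned against a doubled linearization of
    the circle, so clones spanning the origin map to one contiguous
    window; matrix coordinates are then taken modulo the circle length.
    Clones aligning below ``min_identity`` are excluded with a warning.
    """
    ref = reference.sequence
    L = len(ref)
    doubled = ref.residues * 2 if ref.is_circular else ref.residues
    kept_ids: list[str] = []
    kept_rows: list[np.ndarray] = []
    insertions: list[InsertionRecord] = []
    for clone in clones:
        aln, j_start = semiglobal_align(clone, doubled, params)
        identity = aln.n_matches / aln.n_columns
        if identity < min_identity:
            warnings.warn(
                f"clone {clone.id!r} aligns at {identity:.1%} identity "
                f"(< {min_identity:.0%}); excluded as unmappable"
            )
            continue
        row = np.full(L, UNCOVERED, dtype="<U1")
        ref_pos = j_start
        pending_ins: list[str] = []
        for qc, rc in zip(aln.aligned_a, aln.aligned_b):
            if rc == "-":
                pending_ins.append(qc)
                continue
            if pending_ins:
                insertions.append(
                    InsertionRecord(ref_pos % L, clone.id, "".join(pending_ins))
                )
                pending_ins = []
            row[ref_pos % L] = qc if qc != "-" else "-"
            ref_pos += 1
        if pending_ins:
            insertions.append(
                InsertionRecord(ref_pos % L, clone.id, "".join(pending_ins))
            )
        kept_ids.append(clone.id)
        kept_rows.append(row)
    if not kept_rows:
        raise ValueError("no clone could be mapped to the reference")
    return ColumnMatrix(
        reference_id=ref.id,
        reference_residues=ref.residues,
        clone_ids=kept_ids,
        rows=np.vstack(kept_rows),
        insertions=insertions,
    )
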