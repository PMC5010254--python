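"""Cross-species percent identity and conserved-block discovery.

Given a pairwise alignment of homologous regions from two circles, this
module reports percent identity (gap columns count as mismatches) and
extracts maximal runs of gap-free identical columns as candidate
conserved sequence blocks.  A block is *universal* when, in addition to
being identical between the two reference circles, every clone of both
individuals carries exactly the reference sequence across it — the
hallmark of a phylogenetically conserved, presumably functional element.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .align import ColumnMatrix, PairwiseAlignment, UNCOVERED
from .heteroplasmy import round_half_up
from .seq_core import Interval

__all__ = [
    "ConservedBlock",
    "percent_identity",
    "percent_identity_from_counts",
    "find_identical_blocks",
    "universal_blocks",
]


@dataclass(frozen=True)
class ConservedBlock:
    length: int
    position_a: Interval  # ungapped coordinates on sequence a
    position_b: Interval  # ungapped coordinates on sequence b
    context: Optional[str] = None  # gene | noncoding | tRNA
    universal: Optional[bool] = None  # None = undetermined


def percent_identity_from_counts(matches: int, total: int) -> int:
    """Percent identity from match/column counts, rounded to an integer."""
    if total <= 0:
        raise ValueError("total column count must be positive")
    return int(round_half_up(100.0 * matches / total, 0))


def percent_identity(aln: PairwiseAlignment, mode: str = "nt") -> int:
    """Percent identity of an alignment; gap columns count as mismatches.

    ``mode`` records whether nucleotide or amino-acid strings were
    aligned; the computation is identical.
    """
    if mode not in ("nt", "aa"):
        raise ValueError("mode must be 'nt' or 'aa'")
    if aln.n_columns == 0:
        raise ValueError("empty alignment")
    return percent_identity_from_counts(aln.n_matches, aln.n_columns)


def find_identical_blocks(
    aln: PairwiseAlignment, min_len: int = 10, context: Optional[str] = None
) -> list[ConservedBlock]:
    """Maximal runs of gap-free identical columns of length >= ``min_len``.

    Blocks are returned sorted by length descending, then by position on
    sequence a.  Coordinates are ungapped positions on each input.
    """
    if min_len < 1:
        raise ValueError("min_len must be positive")
    blocks = []
    ca = cb = 0  # ungapped cursors
    run_start: Optional[tuple[int, int]] = None
    run_len = 0

    def flush():
        nonlocal run_start, run_len
        if run_start is not None and run_len >= min_len:
            sa, sb = run_start
            blocks.append(
                ConservedBlock(
                    run_len,
                    Interval(sa, sa + run_len),
                    Interval(sb, sb + run_len),
                    context=context,
                )
            )
        run_start, run_len = None, 0

    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == y and x != "-":
            if run_start is None:
                run_start = (ca, cb)
            run_len += 1
        else:
            flush()
        if x != "-":
            ca += 1
        if y != "-":
            cb += 1
    flush()
    blocks.sort(key=lambda b: (-b.length, b.position_a.start))
    return blocks


def _uniform_over(matrix: ColumnMatrix, iv: Interval, offset: int) -> Optional[bool]:
    """True if every clone matches the reference over ``iv`` shifted by ``offset``.

    Returns None when some clone does not cover part of the block, in
    which case universality cannot be determined from this clone set.
    """
    L = matrix.length
    for local in range(iv.start, iv.end):
        pos = (local + offset) % L
        ref = matrix.reference_residues[pos]
        col = matrix.column(pos)
        if any(sym == UNCOVERED for sym in col):
            return None
        if any(sym != ref for sym in col):
            return False
    return True


def universal_blocks(
    blocks: Sequence[ConservedBlock],
    matrix_a: ColumnMatrix,
    matrix_b: ColumnMatrix,
    offset_a: int = 0,
    offset_b: int = 0,
) -> list[ConservedBlock]:
    """Annotate blocks with universality across both individuals' clones.

    ``offset_a``/``offset_b`` translate block-local coordinates (e.g.
    within an excised noncoding region) into the circle coordinates of the
    respective clone matrices.  Blocks partly outside the cloned region
    come back with ``universal=None``.
    """
    out = []
    for b in blocks:
        ua = _uniform_over(matrix_a, b.position_a, offset_a)
        ub = _uniform_over(matrix_b, b.position_b, offset_b)
        universal = None if ua is None or ub is None else (ua and ub)
        out.append(replace(b, universal=universal))
    return out
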