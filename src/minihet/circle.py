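"""Circular minichromosome assembly from an outward-facing amplicon.

The wet-lab design being modelled: a gene is first sequenced internally,
then two primers pointing *outward* from within the gene amplify the
gene-external arc of the putative circle.  If, and only if, both ends of
that amplicon overlap the respective ends of the gene does the molecule
close into a circle.  :func:`merge_amplicon` performs that join in silico
and returns the reconstructed circle, rotated so the gene starts at
position 0.

:func:`length_bookkeeping` checks the published-style accounting identity

    gene + tRNA - overlap + noncoding = circle length

on an annotated circle, where the tRNA typically overlaps the start of the
protein gene by a few bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .seq_core import Interval, NucSequence

__all__ = [
    "Feature",
    "Minicircle",
    "OverlapJoin",
    "LengthBookkeeping",
    "AssemblyError",
    "AmbiguousPlacementError",
    "ConsistencyError",
    "merge_amplicon",
    "length_bookkeeping",
]

FEATURE_TYPES = ("gene", "tRNA", "inverted_repeat", "conserved_block", "noncoding")


class AssemblyError(ValueError):
    """No circularity evidence: a junction overlap could not be found."""


class AmbiguousPlacementError(AssemblyError):
    """An amplicon end matches the gene at more than one locus."""


class ConsistencyError(ValueError):
    """Component lengths do not add up to the circle length."""


@dataclass(frozen=True)
class Feature:
    """Typed feature on a minicircle.

    ``frame`` records the reading-frame offset of a gene with an atypical
    (4-bp) start region; it is 0 for ordinary genes and non-gene features.
    """

    type: str
    interval: Interval
    label: str = ""
    frame: int = 0

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")


@dataclass
class Minicircle:
    """A circular sequence plus its typed feature annotation."""

    sequence: NucSequence
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence.is_circular:
            raise ValueError("Minicircle requires a circular sequence")
        for feat in self.features:
            feat.interval.validate(len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    @property
    def gene(self) -> Feature:
        genes = self.features_of_type("gene")
        if len(genes) != 1:
            raise ValueError(f"expected exactly one gene feature, found {len(genes)}")
        return genes[0]

    def add_feature(self, feat: Feature) -> None:
        feat.interval.validate(len(self.sequence))
        self.features.append(feat)


@dataclass(frozen=True)
class OverlapJoin:
    """Bookkeeping for the two junctions of an amplicon-to-gene join."""

    left_overlap_len: int
    right_overlap_len: int
    left_mismatches: int
    right_mismatches: int


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def merge_amplicon(
    gene_seq: NucSequence,
    amplicon: NucSequence,
    min_overlap: int = 20,
    max_mismatch: int = 0,
    gene_label: str = "gene",
) -> tuple[Minicircle, OverlapJoin]:
    """Join an outward-facing amplicon onto a gene to reconstruct a circle.

    The amplicon must begin with a suffix of the gene (left junction) and
    end with a prefix of the gene (right junction), each overlap at least
    ``min_overlap`` bp with at most ``max_mismatch`` mismatches.  The
    returned circle has length ``len(gene) + len(amplicon) - left - right``
    and carries the gene at the origin.  Circularity is declared only when
    both junctions are found; multiple consistent placements raise an
    ambiguity error rather than silently picking one.
    """
    if gene_seq.is_circular or amplicon.is_circular:
        raise AssemblyError("merge_amplicon expects two linear sequences")
    g, a = gene_seq.residues, amplicon.residues
    G, A = len(g), len(a)
    if min_overlap < 1:
        raise ValueError("min_overlap must be positive")

    left_candidates = [
        l
        for l in range(min_overlap, min(G, A) + 1)
        if _mismatches(a[:l], g[G - l :]) <= max_mismatch
    ]
    right_candidates = [
        r
        for r in range(min_overlap, min(G, A) + 1)
        if _mismatches(a[A - r :], g[:r]) <= max_mismatch
    ]
    pairs = [(l, r) for l in left_candidates for r in right_candidates if l + r <= A]
    if not pairs:
        raise AssemblyError(
            "no circularity evidence: amplicon ends do not overlap the gene "
            f"(min_overlap={min_overlap}, max_mismatch={max_mismatch})"
        )
    if len(pairs) > 1:
        raise AmbiguousPlacementError(
            f"ambiguous amplicon placement; candidate (left,right) overlaps: {pairs}"
        )
    l, r = pairs[0]
    external = a[l : A - r]
    circle_seq = NucSequence(gene_seq.id + "_circle", g + external, "circular")
    circle = Minicircle(
        circle_seq, [Feature("gene", Interval(0, G), gene_label)]
    )
    join = OverlapJoin(
        left_overlap_len=l,
        right_overlap_len=r,
        left_mismatches=_mismatches(a[:l], g[G - l :]),
        right_mismatches=_mismatches(a[A - r :], g[:r]),
    )
    assert len(circle) == G + A - l - r
    return circle, join


@dataclass(frozen=True)
class LengthBookkeeping:
    """Component-sum record for an annotated circle."""

    gene_len: int
    trna_len: int
    overlap_len: int
    noncoding_len: int

    @property
    def total(self) -> int:
        return self.gene_len + self.trna_len - self.overlap_len + self.noncoding_len


def bookkeeping_from_components(
    gene_len: int, trna_len: int, overlap_len: int, noncoding_len: int
) -> int:
    """Circle length implied by published component lengths."""
    return LengthBookkeeping(gene_len, trna_len, overlap_len, noncoding_len).total


def length_bookkeeping(circle: Minicircle) -> LengthBookkeeping:
    """Derive component lengths from annotation and verify they sum to L.

    Overlapping gene/tRNA bases are counted once; ``noncoding_len`` is the
    part of the circle covered by neither.  Raises
    :class:`ConsistencyError` if the identity fails (which would indicate
    inconsistent feature intervals).
    """
    L = len(circle)
    gene = circle.gene
    gene_positions = set(gene.interval.positions(L))
    trna_positions: set[int] = set()
    trna_len = 0
    for t in circle.features_of_type("tRNA"):
        trna_positions |= set(t.interval.positions(L))
        trna_len += t.interval.span(L)
    overlap_len = len(gene_positions & trna_positions)
    noncoding_len = L - len(gene_positions | trna_positions)
    rec = LengthBookkeeping(gene.interval.span(L), trna_len, overlap_len, noncoding_len)
    if rec.total != L:
        raise ConsistencyError(
            f"component sum {rec.total} != circle length {L} "
            f"(gene {rec.gene_len}, tRNA {rec.trna_len}, overlap {rec.overlap_len}, "
            f"noncoding {rec.noncoding_len})"
        )
    return rec


def noncoding_intervals(circle: Minicircle) -> list[Interval]:
    """Maximal circle intervals covered by neither gene nor tRNA."""
    L = len(circle)
    covered = [False] * L
    for f in circle.features:
        if f.type in ("gene", "tRNA"):
            for p in f.interval.positions(L):
                covered[p] = True
    if all(not c for c in covered):
        raise ValueError("circle has no gene/tRNA annotation")
    if all(covered):
        return []
    # runs of uncovered positions; the first and last run join across the origin
    runs: list[list[int]] = []
    for p in range(L):
        if not covered[p]:
            if runs and runs[-1][-1] == p - 1:
                runs[-1].append(p)
            else:
                runs.append([p])
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == L - 1:
        runs[0] = runs.pop() + runs[0]
    out = []
    for run in runs:
        start = run[0]
        end = (start + len(run)) % L
        wraps = start + len(run) > L
        if end == 0 and not wraps:
            end = L
        out.append(Interval(start, end, wraps=wraps))
    return out
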