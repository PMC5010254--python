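"""Nucleotide sequence primitives for circular mitochondrial chromosomes.

This module provides the basic vocabulary used everywhere else in the
package: an immutable nucleotide sequence that knows whether it is linear
or circular, wrap-aware intervals on a circle, translation under the
invertebrate mitochondrial genetic code (NCBI table 5), and classification
of atypical start codons.

Coordinates are 0-based, half-open throughout.  A feature that crosses the
circle origin is represented by an :class:`Interval` with ``wraps=True``
and ``end < start``; its span is ``(L - start) + end`` on a circle of
length ``L``.

Atypical starts matter here because some insect mitochondrial genes do not
begin with ATG/ATA.  Two alternatives are recognised: a 4-bp
tetranucleotide start region ``ATGT`` (hypothesised to be resolved to a
methionine codon by mRNA editing) and a cysteine ``TGT`` start one base
into the same region.  Both imply that the stop-free reading frame begins
at offset 1 rather than offset 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

from Bio.Data import CodonTable

__all__ = [
    "NucSequence",
    "Interval",
    "GeneticCode",
    "StartClassification",
    "SequenceError",
    "TopologyError",
    "reverse_complement",
    "subseq_circular",
    "translate",
    "classify_start",
    "internal_stop_scan",
    "INVERTEBRATE_MITO",
]

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceError(ValueError):
    """Malformed sequence input."""


class TopologyError(SequenceError):
    """Operation requires a different topology (e.g. wrap on a linear sequence)."""


def reverse_complement(residues: str) -> str:
    """Reverse complement of a nucleotide string, IUPAC-aware."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence with linear or circular topology.

    Residues are normalised on construction: uppercased, with U mapped to
    T so RNA-style FASTA input is accepted.  IUPAC ambiguity codes are
    preserved; anything outside the IUPAC alphabet is rejected.
    """

    id: str
    residues: str
    topology: Literal["linear", "circular"] = "linear"

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("U", "T")
        if not norm:
            raise SequenceError(f"empty sequence for record {self.id!r}")
        bad = set(norm) - IUPAC_NUCLEOTIDES
        if bad:
            raise SequenceError(
                f"record {self.id!r} contains non-IUPAC symbols: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, reverse_complement(self.residues), self.topology)


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a (possibly circular) sequence.

    ``wraps=True`` marks a feature crossing the circle origin, in which
    case ``end < start`` and the interval covers ``[start, L) + [0, end)``.
    """

    start: int
    end: int
    wraps: bool = False
    strand: Literal["+", "-"] = "+"

    def span(self, length: int) -> int:
        if self.wraps:
            return (length - self.start) + self.end
        return self.end - self.start

    def validate(self, length: int) -> None:
        if self.wraps:
            if not (0 <= self.end < self.start <= length):
                raise SequenceError(
                    f"invalid wrapping interval [{self.start},{self.end}) on length {length}"
                )
        else:
            if not (0 <= self.start < self.end <= length):
                raise SequenceError(
                    f"invalid interval [{self.start},{self.end}) on length {length}"
                )
        if self.span(length) <= 0:
            raise SequenceError("interval span must be positive")

    def contains(self, pos: int, length: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def offset_of(self, pos: int, length: int) -> int:
        """Distance from interval start to ``pos`` walking forward on the circle."""
        return (pos - self.start) % length

    def positions(self, length: int) -> Iterator[int]:
        """Absolute positions covered by the interval, in walking order."""
        for k in range(self.span(length)):
            yield (self.start + k) % length


def subseq_circular(seq: NucSequence, iv: Interval) -> NucSequence:
    """Extract the residues of ``iv`` from ``seq``, wrap-aware.

    The result is reverse-complemented for minus-strand intervals.
    Requesting a wrapping interval on a linear sequence is a topology
    error.
    """
    L = len(seq)
    iv.validate(L)
    if iv.wraps and not seq.is_circular:
        raise TopologyError(
            f"interval wraps the origin but sequence {seq.id!r} is linear"
        )
    if iv.wraps:
        residues = seq.residues[iv.start :] + seq.residues[: iv.end]
    else:
        residues = seq.residues[iv.start : iv.end]
    if iv.strand == "-":
        residues = reverse_complement(residues)
    return NucSequence(f"{seq.id}:{iv.start}-{iv.end}", residues, "linear")


# ---------------------------------------------------------------------------
# Genetic code


@dataclass(frozen=True)
class GeneticCode:
    """Codon translation table, default NCBI table 5 (invertebrate mito).

    Table 5 differs from the standard code in the assignments that matter
    for arthropod mitochondria: ATA is methionine, TGA is tryptophan and
    AGA/AGG are serine.  Codons containing ambiguity codes translate to
    'X'; stops are '*'.
    """

    table_id: int = 5
    codon_map: dict = field(default_factory=dict, compare=False)
    start_codons: frozenset = field(default=frozenset(), compare=False)

    def __post_init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        cmap = dict(table.forward_table)
        for stop in table.stop_codons:
            cmap[stop] = "*"
        if len(cmap) != 64:
            raise ValueError(f"incomplete codon table {self.table_id}")
        object.__setattr__(self, "codon_map", cmap)
        object.__setattr__(self, "start_codons", frozenset(table.start_codons))

    def amino_acid(self, codon: str) -> str:
        codon = codon.upper()
        if set(codon) - UNAMBIGUOUS:
            return "X"
        return self.codon_map[codon]

    def is_stop(self, codon: str) -> bool:
        return self.amino_acid(codon) == "*"


INVERTEBRATE_MITO = GeneticCode(5)


def translate(
    seq: NucSequence | str, code: GeneticCode = INVERTEBRATE_MITO, frame: int = 0
) -> str:
    """Translate ``seq`` in the given frame (0, 1 or 2).

    Trailing incomplete codons are dropped; stops are emitted as '*' and
    ambiguous codons as 'X'.
    """
    residues = seq.residues if isinstance(seq, NucSequence) else seq.upper()
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if len(residues) - frame < 3:
        raise SequenceError("sequence too short to translate in this frame")
    n_codons = (len(residues) - frame) // 3
    return "".join(
        code.amino_acid(residues[frame + 3 * k : frame + 3 * k + 3])
        for k in range(n_codons)
    )


def internal_stop_scan(
    seq: NucSequence | str, code: GeneticCode = INVERTEBRATE_MITO, frame: int = 0
) -> list[int]:
    """0-based codon indices whose codon is a stop.

    A clean gene returns exactly one index, pointing at the final codon.
    """
    aa = translate(seq, code, frame)
    return [i for i, sym in enumerate(aa) if sym == "*"]


def _stop_free_internally(residues: str, code: GeneticCode, frame: int) -> bool:
    """True when no stop codon occurs before the final codon of the frame."""
    if len(residues) - frame < 3:
        return True
    stops = internal_stop_scan(residues, code, frame)
    n_codons = (len(residues) - frame) // 3
    return all(idx == n_codons - 1 for idx in stops)


# ---------------------------------------------------------------------------
# Start-codon classification


@dataclass(frozen=True)
class StartClassification:
    """Inferred start type of a protein gene.

    ``offset`` is the frame offset of the stop-free reading: 0 for a
    standard ATG/ATA start, 1 for both atypical readings (the 4-bp ATGT
    start region and the cysteine TGT start one base in).  When the ATGT
    reading is chosen and the TGT reading is equally stop-free, the latter
    is reported in ``alternative``.
    """

    category: Literal["standard_ATG", "tetranucleotide_ATGT", "cysteine_TGT", "other"]
    offset: int
    alternative: Optional[str] = None


def classify_start(
    gene_seq: NucSequence | str, code: GeneticCode = INVERTEBRATE_MITO
) -> StartClassification:
    """Classify the start of a protein gene sequence.

    Order of precedence: a 4-bp ATGT start is reported when the offset-1
    frame is internally stop-free while the offset-0 frame is not (a gene
    whose offset-0 frame is clean simply starts with ATG); then a standard
    ATG/ATA first codon; then a cysteine TGT start at offset 1 with a
    stop-free offset-1 frame; otherwise ``other``.
    """
    residues = (
        gene_seq.residues if isinstance(gene_seq, NucSequence) else gene_seq.upper()
    )
    if len(residues) < 4:
        raise SequenceError("gene shorter than 4 bp cannot be classified")

    first_codon = residues[:3]
    offset1_clean = _stop_free_internally(residues, code, 1)
    offset0_clean = _stop_free_internally(residues, code, 0)

    if residues[:4] == "ATGT" and offset1_clean and not offset0_clean:
        # The TGT cysteine reading uses the same offset-1 frame, so it is
        # always available as the alternative interpretation.
        return StartClassification(
            "tetranucleotide_ATGT", offset=1, alternative="cysteine_TGT"
        )
    if first_codon in ("ATG", "ATA"):
        return StartClassification("standard_ATG", offset=0)
    if residues[1:4] == "TGT" and offset1_clean:
        return StartClassification("cysteine_TGT", offset=1)
    return StartClassification("other", offset=0)
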