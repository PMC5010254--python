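"""Heteroplasmic site calling and summary statistics for clone sets.

A heteroplasmic site is a reference column where at least two distinct
unambiguous bases occur among the clones of one individual.  Gaps and
IUPAC ambiguity codes neither create nor join sites — an uncertain base
call is never evidence of heteroplasmy.  Sites are classified by region
(coding, tRNA, their overlap, or noncoding) and, inside the gene, by codon
position.

The headline statistic is heteroplasmic sites per bp per clone,

    rate = sites / (n_clones * surveyed_bp),

where ``surveyed_bp`` counts only reference positions covered by *every*
clone, so individuals sequenced to different extents remain comparable.
Following the published convention the rate is reported rounded half-up
to 4 decimals, and sites per clone to 1 decimal.

Sites falling in the gene/tRNA overlap are reported under the ``overlap``
region and included in BOTH the coding tallies (and the rate denominator)
and the tRNA tally; the report flags this double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .align import ColumnMatrix, InsertionRecord, UNCOVERED
from .circle import Minicircle
from .seq_core import (
    GeneticCode,
    INVERTEBRATE_MITO,
    NucSequence,
    translate,
)

__all__ = [
    "HeteroplasmicSite",
    "IndelEvent",
    "FrameshiftCall",
    "HeteroplasmyReport",
    "call_sites",
    "rate",
    "sites_per_clone",
    "detect_frameshifts",
    "replacement_substitutions",
    "unique_replacement_substitutions",
    "unique_clone_count",
    "taq_error_expectation",
    "build_report",
    "round_half_up",
]

_BASES = set("ACGT")


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed summary values are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HeteroplasmicSite:
    ref_pos: int
    region: str  # coding | tRNA | overlap | noncoding
    codon_position: Optional[int]  # 1|2|3 inside the gene, else None
    alleles: dict  # base -> clone count

    def __post_init__(self) -> None:
        if len([b for b in self.alleles if b in _BASES]) < 2:
            raise ValueError("a heteroplasmic site needs >=2 distinct bases")


@dataclass(frozen=True)
class IndelEvent:
    ref_pos: int
    length: int
    clone_id: str
    kind: str  # "ins" | "del"


@dataclass(frozen=True)
class FrameshiftCall:
    clone_id: str
    net_indel_len: int
    truncated_protein_len: int


def classify_position(pos: int, circle: Minicircle) -> tuple[str, Optional[int]]:
    """Region and codon position of a reference position.

    Codon position is computed from the gene start, shifted by the gene's
    reading-frame offset (nonzero for a 4-bp start region).
    """
    L = len(circle)
    gene = circle.gene
    in_gene = gene.interval.contains(pos, L)
    in_trna = any(
        t.interval.contains(pos, L) for t in circle.features_of_type("tRNA")
    )
    if in_gene:
        offset = gene.interval.offset_of(pos, L)
        codon_pos = ((offset - gene.frame) % 3) + 1
        return ("overlap" if in_trna else "coding"), codon_pos
    if in_trna:
        return "tRNA", None
    return "noncoding", None


def call_sites(matrix: ColumnMatrix, circle: Minicircle) -> list[HeteroplasmicSite]:
    """Call heteroplasmic sites from a reference-coordinate clone matrix."""
    if not circle.features_of_type("gene"):
        raise ValueError("circle annotation must include the gene feature")
    sites = []
    for pos in range(matrix.length):
        counts: dict[str, int] = {}
        for sym in matrix.column(pos):
            if sym in _BASES:
                counts[sym] = counts.get(sym, 0) + 1
        if len(counts) >= 2:
            region, codon_pos = classify_position(pos, circle)
            sites.append(HeteroplasmicSite(pos, region, codon_pos, counts))
    return sites


def rate(sites: int, n_clones: int, surveyed_bp: int) -> float:
    """Heteroplasmic sites per bp per clone, rounded half-up to 4 decimals."""
    if n_clones <= 0 or surveyed_bp <= 0:
        raise ValueError("rate requires positive clone count and surveyed bp")
    if sites < 0:
        raise ValueError("negative site count")
    return round_half_up(sites / (n_clones * surveyed_bp), 4)


def sites_per_clone(sites: int, n_clones: int) -> float:
    """Sites per clone, rounded half-up to 1 decimal."""
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    return round_half_up(sites / n_clones, 1)


def taq_error_expectation(error_rate: float, bp: int) -> float:
    """Expected polymerase errors over ``bp`` bases, 1 decimal.

    Used to check that the enzyme's error rate cannot account for the
    observed heteroplasmy.
    """
    if error_rate < 0:
        raise ValueError("error rate must be non-negative")
    return round_half_up(error_rate * bp, 1)


def unique_clone_count(clones: Sequence[NucSequence]) -> int:
    """Number of distinct clone sequences (exact string equality)."""
    if not clones:
        raise ValueError("need at least one clone")
    return len({c.residues for c in clones})


# ---------------------------------------------------------------------------
# Indels, frameshifts and replacement substitutions


def indel_events(matrix: ColumnMatrix) -> list[IndelEvent]:
    """All insertion and deletion events relative to the reference."""
    events = [
        IndelEvent(r.ref_pos, len(r.inserted), r.clone_id, "ins")
        for r in matrix.insertions
    ]
    L = matrix.length
    for ci, clone_id in enumerate(matrix.clone_ids):
        row = matrix.rows[ci]
        pos = 0
        while pos < L:
            if row[pos] == "-":
                start = pos
                while pos < L and row[pos] == "-":
                    pos += 1
                events.append(IndelEvent(start, pos - start, clone_id, "del"))
            else:
                pos += 1
    return events


def _clone_gene_sequence(matrix: ColumnMatrix, clone_idx: int, circle: Minicircle) -> str:
    """Reconstruct a clone's version of the gene region.

    Positions the clone does not cover fall back to the reference base, so
    partial clones still yield a translatable gene; deletions are removed
    and insertions spliced in.
    """
    L = len(circle)
    gene = circle.gene
    clone_id = matrix.clone_ids[clone_idx]
    ins_at: dict[int, str] = {}
    for r in matrix.insertions:
        if r.clone_id == clone_id:
            ins_at[r.ref_pos] = ins_at.get(r.ref_pos, "") + r.inserted
    out: list[str] = []
    for pos in gene.interval.positions(L):
        if pos in ins_at:
            out.append(ins_at[pos])
        sym = matrix.rows[clone_idx, pos]
        if sym == UNCOVERED:
            out.append(matrix.reference_residues[pos])
        elif sym != "-":
            out.append(sym)
    return "".join(out)


def detect_frameshifts(
    matrix: ColumnMatrix,
    circle: Minicircle,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> list[FrameshiftCall]:
    """Clones whose net indel length within the gene is not a multiple of 3.

    For each frameshifted clone the truncated-protein length is the number
    of codons translated before the first stop in the shifted frame.
    """
    L = len(circle)
    gene = circle.gene
    events = indel_events(matrix)
    calls = []
    for ci, clone_id in enumerate(matrix.clone_ids):
        net = 0
        for ev in events:
            if ev.clone_id != clone_id:
                continue
            if gene.interval.contains(ev.ref_pos, L):
                net += ev.length if ev.kind == "ins" else -ev.length
        if net % 3 == 0:
            continue
        gene_seq = _clone_gene_sequence(matrix, ci, circle)
        aa = translate(gene_seq, code, frame=gene.frame)
        truncated = aa.index("*") if "*" in aa else len(aa)
        calls.append(FrameshiftCall(clone_id, net, truncated))
    return calls


def replacement_substitutions(
    matrix: ColumnMatrix,
    circle: Minicircle,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> dict[str, list[tuple[int, str, str]]]:
    """Amino-acid differences of each non-frameshifted clone vs the reference.

    Returns ``{clone_id: [(aa_position_1based, ref_aa, clone_aa), ...]}``.
    Frameshifted clones are excluded (reported separately by
    :func:`detect_frameshifts`); 'X' columns from ambiguous bases are
    ignored.
    """
    gene = circle.gene
    shifted = {c.clone_id for c in detect_frameshifts(matrix, circle, code)}
    ref_gene = "".join(
        matrix.reference_residues[p] for p in gene.interval.positions(len(circle))
    )
    ref_aa = translate(ref_gene, code, frame=gene.frame)
    out: dict[str, list[tuple[int, str, str]]] = {}
    for ci, clone_id in enumerate(matrix.clone_ids):
        if clone_id in shifted:
            continue
        aa = translate(
            _clone_gene_sequence(matrix, ci, circle), code, frame=gene.frame
        )
        diffs = [
            (k + 1, r, c)
            for k, (r, c) in enumerate(zip(ref_aa, aa))
            if r != c and "X" not in (r, c)
        ]
        out[clone_id] = diffs
    return out


def unique_replacement_substitutions(
    subs: dict[str, list[tuple[int, str, str]]]
) -> dict[str, list[tuple[int, str, str]]]:
    """Filter to substitutions not shared (position, amino acid) with any other clone."""
    tally: dict[tuple[int, str], int] = {}
    for diffs in subs.values():
        for pos, _r, c in diffs:
            tally[(pos, c)] = tally.get((pos, c), 0) + 1
    return {
        clone: [d for d in diffs if tally[(d[0], d[2])] == 1]
        for clone, diffs in subs.items()
    }


# ---------------------------------------------------------------------------
# Report


@dataclass
class HeteroplasmyReport:
    n_clones: int
    surveyed_bp: dict  # region -> bp covered by all clones
    site_counts: dict  # region -> number of sites
    codon_position_counts: dict  # 1|2|3 -> count (coding + overlap)
    indel_events: list
    frameshifts: list
    unique_clone_count: int
    rate_raw: float
    rate: float
    sites: list
    noncoding_length_range: tuple
    overlap_double_counted: bool = True

    def to_dict(self) -> dict:
        return {
            "n_clones": self.n_clones,
            "surveyed_bp": dict(self.surveyed_bp),
            "site_counts": dict(self.site_counts),
            "codon_position_counts": {
                str(k): v for k, v in self.codon_position_counts.items()
            },
            "n_indel_events": len(self.indel_events),
            "frameshift_clones": [
                {
                    "clone_id": c.clone_id,
                    "net_indel_len": c.net_indel_len,
                    "truncated_protein_len": c.truncated_protein_len,
                }
                for c in self.frameshifts
            ],
            "unique_clone_count": self.unique_clone_count,
            "rate_per_bp_per_clone": self.rate,
            "rate_per_bp_per_clone_raw": self.rate_raw,
            "noncoding_length_range": list(self.noncoding_length_range),
            "overlap_double_counted": self.overlap_double_counted,
        }


def _noncoding_clone_lengths(matrix: ColumnMatrix, circle: Minicircle) -> list[int]:
    L = len(circle)
    nc_positions = [
        p for p in range(L) if classify_position(p, circle)[0] == "noncoding"
    ]
    nc_set = set(nc_positions)
    lengths = []
    for ci, clone_id in enumerate(matrix.clone_ids):
        base_count = sum(
            1 for p in nc_positions if matrix.rows[ci, p] in _BASES
        )
        ins_count = sum(
            len(r.inserted)
            for r in matrix.insertions
            if r.clone_id == clone_id and r.ref_pos in nc_set
        )
        lengths.append(base_count + ins_count)
    return lengths


def build_report(
    matrix: ColumnMatrix,
    circle: Minicircle,
    clones: Optional[Sequence[NucSequence]] = None,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> HeteroplasmyReport:
    """Assemble the full heteroplasmy summary for one individual.

    The rate denominator uses coding surveyed bp (coding plus the
    gene/tRNA overlap), restricted to positions covered by every clone.
    """
    sites = call_sites(matrix, circle)
    covered_all = matrix.covered_by_all()
    surveyed = {"coding": 0, "tRNA": 0, "overlap": 0, "noncoding": 0}
    for pos in range(matrix.length):
        if covered_all[pos]:
            region, _ = classify_position(pos, circle)
            surveyed[region] += 1
    site_counts = {"coding": 0, "tRNA": 0, "overlap": 0, "noncoding": 0}
    codon_counts = {1: 0, 2: 0, 3: 0}
    for s in sites:
        site_counts[s.region] += 1
        if s.codon_position is not None:
            codon_counts[s.codon_position] += 1
    coding_sites = site_counts["coding"] + site_counts["overlap"]
    coding_bp = surveyed["coding"] + surveyed["overlap"]
    raw = coding_sites / (matrix.n_clones * coding_bp) if coding_bp else 0.0
    nc_lengths = _noncoding_clone_lengths(matrix, circle)
    if clones is not None:
        n_unique = unique_clone_count(clones)
    else:
        keys = {
            (matrix.row_string(i), tuple(sorted(
                (r.ref_pos, r.inserted)
                for r in matrix.insertions
                if r.clone_id == matrix.clone_ids[i]
            )))
            for i in range(matrix.n_clones)
        }
        n_unique = len(keys)
    return HeteroplasmyReport(
        n_clones=matrix.n_clones,
        surveyed_bp=surveyed,
        site_counts=site_counts,
        codon_position_counts=codon_counts,
        indel_events=indel_events(matrix),
        frameshifts=detect_frameshifts(matrix, circle, code),
        unique_clone_count=n_unique,
        rate_raw=raw,
        rate=round_half_up(raw, 4),
        sites=sites,
        noncoding_length_range=(min(nc_lengths), max(nc_lengths)),
    )
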