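"""Synthetic minicircles and heteroplasmic clone sets.

The generator emulates the organisation of a louse-type mitochondrial
*cox1* minicircle: a ~1.9-kb circle carrying one protein gene of 512
codons starting at the origin, a tRNA gene whose 3' end overlaps the gene
start by a few bases, and a noncoding region containing a planted
inverted repeat (candidate replication origin) and two conserved motifs
(19 bp and 11 bp) placed a fixed distance after the gene's stop codon.

Two presets mirror the two organisations the pipeline is designed
around::

    G_AUREI  gene 1,536 bp (ATG start), tRNA 68 bp, overlap 6 bp,
             noncoding 316 bp  -> circle 1,914 bp
    T_MINOR  gene 1,537 bp (ATGT 4-bp start region), tRNA 65 bp,
             overlap 4 bp, noncoding 307 bp -> circle 1,905 bp

Clones cover the amplified arc produced by outward-facing PCR — the
noncoding region plus flanks of the gene amounting to 591 coding bp —
and receive i.i.d. per-site substitutions at region-specific rates,
noncoding indels, and a configurable number of coding frameshift indels.
Planted motifs and inverted-repeat arms are excluded from mutation, and
the repeat arms are buffered by short non-self-complementary (poly-A)
guards so the planted repeat is recovered with exact coordinates.  Every
mutation event is recorded in a ground-truth object that tests use as an
oracle.

All randomness flows from a single seeded NumPy generator, so a given
seed reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .circle import Feature, Minicircle
from .seq_core import Interval, NucSequence, reverse_complement, INVERTEBRATE_MITO

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimBundle",
    "G_AUREI",
    "T_MINOR",
    "generate_minicircle",
    "generate_clones",
    "generate_bundle",
    "generate_species_pair",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated individual.

    Substitution probabilities are per site per clone.  The coding default
    0.0017 and the tRNA default 0.0011 correspond to the per-bp-per-clone
    heteroplasmy levels the pipeline is meant to resolve; the noncoding
    default 0.01 makes noncoding variation dominate, as observed for such
    circles.  Noncoding indel counts are Poisson per clone with lengths
    uniform on 1..8 bp, giving clone noncoding lengths that vary over a
    range of roughly 15-25 bp.
    """

    seed: int = 0
    gene_codons: int = 512  # codons including the terminal stop
    start_type: str = "ATG"  # ATG | ATGT | TGT
    trna_len: int = 68
    trna_overlap: int = 6
    noncoding_len: int = 316
    ir_arm: int = 30
    ir_spacer: int = 31
    motif_lens: tuple = (19, 11)
    motif_offset: int = 19  # bp between stop codon and first motif
    motif_gap: int = 15  # bp between the two motifs
    n_clones: int = 26
    p_coding: float = 0.0017
    p_trna: float = 0.0011
    p_noncoding: float = 0.01
    nc_indel_mean: float = 2.0
    nc_indel_max_len: int = 8
    n_frameshift_clones: int = 2
    coding_left_flank: int = 100  # gene bp covered after the origin
    coding_right_flank: int = 491  # gene bp covered before the gene end

    @property
    def gene_span(self) -> int:
        span = 3 * self.gene_codons
        # both atypical starts carry one extra leading base (4-bp start
        # region, or a pad before the offset-1 cysteine codon)
        return span + 1 if self.start_type in ("ATGT", "TGT") else span

    @property
    def gene_frame(self) -> int:
        return 1 if self.start_type in ("ATGT", "TGT") else 0

    @property
    def circle_length(self) -> int:
        return self.gene_span + self.trna_len - self.trna_overlap + self.noncoding_len

    def validate(self) -> None:
        if self.gene_codons < 10:
            raise ValueError("gene too short")
        for p in (self.p_coding, self.p_trna, self.p_noncoding):
            if not 0 <= p <= 1:
                raise ValueError("substitution probabilities must be in [0,1]")
        ir_total = 2 * self.ir_arm + self.ir_spacer + 12  # incl. poly-A guards
        motifs_total = self.motif_offset + sum(self.motif_lens) + self.motif_gap
        if motifs_total + ir_total > self.noncoding_len:
            raise ValueError(
                "noncoding region too short for planted motifs and inverted repeat"
            )
        if self.trna_overlap >= self.trna_len:
            raise ValueError("tRNA overlap exceeds tRNA length")
        if self.coding_left_flank + self.coding_right_flank >= self.gene_span:
            raise ValueError("coding flanks exceed the gene")


G_AUREI = SimConfig()
T_MINOR = SimConfig(
    start_type="ATGT",
    trna_len=65,
    trna_overlap=4,
    noncoding_len=307,
    ir_arm=14,
    ir_spacer=10,
    motif_offset=24,
    n_clones=12,
    p_coding=0.0014,
    p_trna=0.0038,
    n_frameshift_clones=0,
)


@dataclass
class GroundTruth:
    """Planted events, used by tests as the oracle for every stage."""

    substitutions: dict = field(default_factory=dict)  # clone -> [(pos, ref, alt)]
    indels: dict = field(default_factory=dict)  # clone -> [(pos, len, kind)]
    frameshift_clones: list = field(default_factory=list)
    ir_arm1: Optional[Interval] = None
    ir_arm2: Optional[Interval] = None
    motifs: list = field(default_factory=list)  # [Interval] on the circle
    arc: Optional[Interval] = None

    def to_dict(self) -> dict:
        def iv(x):
            return None if x is None else dataclasses.asdict(x)

        return {
            "substitutions": self.substitutions,
            "indels": self.indels,
            "frameshift_clones": self.frameshift_clones,
            "ir_arm1": iv(self.ir_arm1),
            "ir_arm2": iv(self.ir_arm2),
            "motifs": [dataclasses.asdict(m) for m in self.motifs],
            "arc": iv(self.arc),
        }


@dataclass
class SimBundle:
    circle: Minicircle
    clones: list
    truth: GroundTruth
    config: SimConfig


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop codons."""
    out = []
    while len(out) < n:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _make_gene(cfg: SimConfig, rng: np.random.Generator, body: Optional[str]) -> str:
    """Gene sequence with the configured start type and a clean reading frame."""
    n_body = cfg.gene_codons - 2  # minus start and stop codons
    for _ in range(200):
        b = body if body is not None else _random_codons(rng, n_body)
        if cfg.start_type == "ATG":
            gene = "ATG" + b + "TAG"
            return gene
        if cfg.start_type == "TGT":
            head = "TGT"
            gene_core = head + b + "TAA"
            gene = rng.choice(list("CG")) + gene_core  # pad to keep frame offset 1
        elif cfg.start_type == "ATGT":
            gene = "ATGT" + b + "TAA"
        else:
            raise ValueError(f"unknown start type {cfg.start_type!r}")
        # the offset-0 frame must hit a stop, otherwise the start would be
        # read as a standard ATG; with >500 shifted codons this holds for
        # essentially every random body
        frame0 = [gene[k : k + 3] for k in range(0, len(gene) - 2, 3)]
        if any(c in _STOPS for c in frame0[:-1]):
            return gene
        body = None  # resample
    raise RuntimeError("could not generate a gene with the requested start type")


def generate_minicircle(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    motifs: Optional[tuple] = None,
    gene_body: Optional[str] = None,
    trna_core: Optional[str] = None,
    label: str = "sim",
    motif_flank_base: Optional[str] = None,
) -> tuple[Minicircle, GroundTruth]:
    """Build one annotated circle and the ground truth of planted elements.

    ``motifs`` may supply pre-drawn conserved motif sequences so two
    species share them; ``gene_body``/``trna_core`` likewise allow a
    second circle to reuse (mutated) material from a first.
    ``motif_flank_base`` pins the single base on each side of every motif
    (species pairs use different bases so that a conserved block ends
    exactly at the planted motif boundary).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    gene = _make_gene(cfg, rng, gene_body)
    G = cfg.gene_span
    NC = cfg.noncoding_len
    L = cfg.circle_length

    if motifs is None:
        motifs = tuple(_random_seq(rng, m) for m in cfg.motif_lens)
    if any(len(m) != l for m, l in zip(motifs, cfg.motif_lens)):
        raise ValueError("motif lengths disagree with configuration")

    # --- noncoding layout (local coordinates within [0, NC)) ---
    m1_start = cfg.motif_offset
    m2_start = m1_start + len(motifs[0]) + cfg.motif_gap
    motifs_end = m2_start + len(motifs[1])
    ir_total = 2 * cfg.ir_arm + cfg.ir_spacer
    guard = 6
    ir_start = motifs_end + guard + (NC - motifs_end - ir_total - 2 * guard) // 2
    arm1_local = (ir_start, ir_start + cfg.ir_arm)
    arm2_local = (ir_start + cfg.ir_arm + cfg.ir_spacer, ir_start + ir_total)

    nc = list(_random_seq(rng, NC))
    nc[m1_start : m1_start + len(motifs[0])] = motifs[0]
    nc[m2_start : m2_start + len(motifs[1])] = motifs[1]
    if motif_flank_base is not None:
        for start, mot in ((m1_start, motifs[0]), (m2_start, motifs[1])):
            nc[start - 1] = motif_flank_base
            nc[start + len(mot)] = motif_flank_base
    arm = _random_seq(rng, cfg.ir_arm)
    nc[arm1_local[0] : arm1_local[1]] = arm
    nc[arm2_local[0] : arm2_local[1]] = reverse_complement(arm)
    # poly-A guards and spacer: adenines cannot pair with each other, so
    # the planted arms cannot extend by chance into their surroundings
    nc[arm1_local[0] - guard : arm1_local[0]] = "A" * guard
    nc[arm1_local[1] : arm2_local[0]] = "A" * cfg.ir_spacer
    nc[arm2_local[1] : arm2_local[1] + guard] = "A" * guard
    nc_seq = "".join(nc)
    if len(nc_seq) != NC:
        raise RuntimeError("noncoding assembly error")

    # --- tRNA: its last `overlap` bases are the first bases of the gene ---
    t_core_len = cfg.trna_len - cfg.trna_overlap
    t_core = trna_core if trna_core is not None else _random_seq(rng, t_core_len)
    if len(t_core) != t_core_len:
        raise ValueError("tRNA core length disagrees with configuration")

    residues = gene + nc_seq + t_core
    assert len(residues) == L
    seq = NucSequence(label, residues, "circular")
    trna_iv = Interval(G + NC, cfg.trna_overlap, wraps=True)
    features = [
        Feature("gene", Interval(0, G), "cox1-like", frame=cfg.gene_frame),
        Feature("tRNA", trna_iv, "trnI-like"),
        Feature("noncoding", Interval(G, G + NC), "noncoding"),
    ]
    truth = GroundTruth(
        ir_arm1=Interval(G + arm1_local[0], G + arm1_local[1]),
        ir_arm2=Interval(G + arm2_local[0], G + arm2_local[1]),
        motifs=[
            Interval(G + m1_start, G + m1_start + len(motifs[0])),
            Interval(G + m2_start, G + m2_start + len(motifs[1])),
        ],
    )
    circle = Minicircle(seq, features)
    circle.add_feature(
        Feature("inverted_repeat", truth.ir_arm1, "IR-arm1")
    )
    circle.add_feature(
        Feature("inverted_repeat", truth.ir_arm2, "IR-arm2")
    )
    return circle, truth


def _arc_interval(cfg: SimConfig) -> Interval:
    start = cfg.gene_span - cfg.coding_right_flank
    return Interval(start, cfg.coding_left_flank, wraps=True)


def generate_clones(
    circle: Minicircle,
    cfg: SimConfig,
    truth: GroundTruth,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[NucSequence], GroundTruth]:
    """Simulate the cloned amplicon set for one individual.

    Every clone covers the same amplified arc.  Substitutions are i.i.d.
    per site at the rate of the site's region; noncoding indels are drawn
    per clone; the first ``n_frameshift_clones`` clone indices drawn at
    random receive a single 1-bp coding indel.  All events land in the
    returned ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    L = len(circle)
    arc = _arc_interval(cfg)
    truth.arc = arc
    gene_iv = circle.gene.interval
    trna_ivs = [f.interval for f in circle.features_of_type("tRNA")]

    masked = set()
    for iv in truth.motifs + [truth.ir_arm1, truth.ir_arm2]:
        if iv is not None:
            masked.update(iv.positions(L))

    def region_rate(pos: int) -> float:
        if gene_iv.contains(pos, L):
            return cfg.p_coding
        if any(iv.contains(pos, L) for iv in trna_ivs):
            return cfg.p_trna
        return cfg.p_noncoding

    arc_positions = list(arc.positions(L))
    nc_positions = [
        p
        for p in arc_positions
        if not gene_iv.contains(p, L)
        and not any(iv.contains(p, L) for iv in trna_ivs)
        and p not in masked
    ]
    # indels are planted only in the noncoding interior: an indel flush
    # against a region boundary cannot be unambiguously attributed to
    # either side by any alignment, so events there would make the
    # ground truth ill-defined
    guard = cfg.nc_indel_max_len + 2
    nc_feats = [f.interval for f in circle.features_of_type("noncoding")]
    interior = set()
    for iv in nc_feats:
        span = iv.span(L)
        interior.update(
            (iv.start + k) % L for k in range(guard, max(guard, span - guard))
        )
    nc_indel_positions = [p for p in nc_positions if p in interior]
    nc_indel_set = set(nc_indel_positions)
    coding_positions = [p for p in arc_positions if gene_iv.contains(p, L)]

    if cfg.n_frameshift_clones > cfg.n_clones:
        raise ValueError("more frameshift clones than clones")
    fs_clones = sorted(
        int(i)
        for i in rng.choice(cfg.n_clones, size=cfg.n_frameshift_clones, replace=False)
    )

    ref = circle.sequence.residues
    clones = []
    for c in range(cfg.n_clones):
        clone_id = f"clone_{c + 1:02d}"
        subs = []
        for p in arc_positions:
            if p in masked:
                continue
            if rng.random() < region_rate(p):
                alt = str(rng.choice([b for b in "ACGT" if b != ref[p]]))
                subs.append((p, ref[p], alt))
        indels = []
        n_ind = int(rng.poisson(cfg.nc_indel_mean))
        for _ in range(n_ind):
            if not nc_indel_positions:
                break
            length = int(rng.integers(1, cfg.nc_indel_max_len + 1))
            kind = "del" if rng.random() < 0.5 else "ins"
            pos = int(rng.choice(nc_indel_positions))
            if kind == "del":
                run = [(pos + k) % L for k in range(length)]
                if any(q not in nc_indel_set for q in run):
                    continue  # would clip a planted element; skip the event
                indels.append((pos, length, "del"))
            else:
                indels.append((pos, length, "ins", _random_seq(rng, length)))
        if c in fs_clones:
            # a single 1-bp coding indel, away from the gene start
            interior = [
                p
                for p in coding_positions
                if 10 <= gene_iv.offset_of(p, L) <= gene_iv.span(L) - 10
            ]
            pos = int(rng.choice(interior))
            if rng.random() < 0.5:
                indels.append((pos, 1, "del"))
            else:
                indels.append((pos, 1, "ins", _random_seq(rng, 1)))

        sub_at = {p: alt for p, _, alt in subs}
        del_at: set[int] = set()
        ins_at: dict[int, str] = {}
        for ev in indels:
            if ev[2] == "del":
                for k in range(ev[1]):
                    del_at.add((ev[0] + k) % L)
            else:
                ins_at[ev[0]] = ins_at.get(ev[0], "") + ev[3]
        out = []
        for p in arc_positions:
            if p in ins_at:
                out.append(ins_at[p])
            if p in del_at:
                continue
            out.append(sub_at.get(p, ref[p]))
        clones.append(NucSequence(clone_id, "".join(out), "linear"))
        truth.substitutions[clone_id] = subs
        truth.indels[clone_id] = [list(ev) for ev in indels]
        if c in fs_clones:
            truth.frameshift_clones.append(clone_id)
    return clones, truth


def generate_bundle(cfg: SimConfig, label: str = "sim") -> SimBundle:
    """One individual: circle, clones and ground truth from a single seed."""
    rng = np.random.default_rng(cfg.seed)
    circle, truth = generate_minicircle(cfg, rng, label=label)
    clones, truth = generate_clones(circle, cfg, truth, rng)
    return SimBundle(circle, clones, truth, cfg)


def _mutate_seq(s: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site mutation of a nucleotide string."""
    chars = list(s)
    for k in range(len(chars)):
        if rng.random() < rate:
            chars[k] = str(rng.choice([b for b in "ACGT" if b != chars[k]]))
    return "".join(chars)


def _diverge_codons(
    body: str,
    rng: np.random.Generator,
    q_nonsyn: float = 0.15,
    q_syn: float = 0.38,
) -> str:
    """Codon-aware divergence of a gene body.

    Each codon is replaced by a random codon encoding a *different* amino
    acid with probability ``q_nonsyn`` or by a synonymous codon with
    probability ``q_syn``.  The defaults emulate the typical pattern of
    between-species mitochondrial gene divergence, where silent changes
    dominate and amino-acid identity (about 85%) is much higher than
    nucleotide identity (about 76%).
    """
    code = INVERTEBRATE_MITO
    sense = [c for c in map("".join, itertools.product("ACGT", repeat=3))
             if c not in _STOPS]
    by_aa: dict[str, list[str]] = {}
    for c in sense:
        by_aa.setdefault(code.amino_acid(c), []).append(c)
    out = []
    for k in range(0, len(body) - 2, 3):
        codon = body[k : k + 3]
        aa = code.amino_acid(codon)
        r = rng.random()
        if r < q_nonsyn:
            choices = [c for c in sense if code.amino_acid(c) != aa]
            out.append(str(rng.choice(choices)))
        elif r < q_nonsyn + q_syn:
            syn = [c for c in by_aa[aa] if c != codon]
            out.append(str(rng.choice(syn)) if syn else codon)
        else:
            out.append(codon)
    return "".join(out)


def generate_species_pair(
    seed: int,
    cfg_a: SimConfig = G_AUREI,
    cfg_b: SimConfig = T_MINOR,
    q_nonsyn: float = 0.15,
    q_syn: float = 0.38,
    trna_divergence: float = 0.10,
) -> tuple[SimBundle, SimBundle]:
    """Two individuals from related species sharing conserved motifs.

    Species B's gene and tRNA are diverged copies of species A's (the
    gene codon-aware, so silent changes dominate); the conserved 19-bp
    and 11-bp motifs are planted identically in both noncoding regions,
    flanked by deterministically different bases in the two species, and
    everything else in the noncoding region is drawn independently —
    mirroring genuinely conserved blocks inside otherwise dissimilar
    noncoding DNA.
    """
    rng = np.random.default_rng(seed)
    motifs = tuple(_random_seq(rng, m) for m in cfg_a.motif_lens)

    cfg_a = replace(cfg_a, seed=int(rng.integers(2**31 - 1)))
    rng_a = np.random.default_rng(cfg_a.seed)
    circle_a, truth_a = generate_minicircle(
        cfg_a, rng_a, motifs=motifs, label="speciesA", motif_flank_base="A"
    )
    clones_a, truth_a = generate_clones(circle_a, cfg_a, truth_a, rng_a)

    body_a = circle_a.sequence.residues[
        3 if cfg_a.start_type == "ATG" else 4 : cfg_a.gene_span - 3
    ]
    body_b = _diverge_codons(body_a, rng, q_nonsyn, q_syn)
    core_a = circle_a.sequence.residues[cfg_a.gene_span + cfg_a.noncoding_len :]
    core_b = _mutate_seq(core_a, trna_divergence, rng)
    t_core_len_b = cfg_b.trna_len - cfg_b.trna_overlap
    if len(core_b) > t_core_len_b:
        core_b = core_b[: t_core_len_b]
    else:
        core_b = core_b + _random_seq(rng, t_core_len_b - len(core_b))

    cfg_b = replace(cfg_b, seed=int(rng.integers(2**31 - 1)))
    rng_b = np.random.default_rng(cfg_b.seed)
    circle_b, truth_b = generate_minicircle(
        cfg_b, rng_b, motifs=motifs, gene_body=body_b, trna_core=core_b,
        label="speciesB", motif_flank_base="C",
    )
    clones_b, truth_b = generate_clones(circle_b, cfg_b, truth_b, rng_b)
    return (
        SimBundle(circle_a, clones_a, truth_a, cfg_a),
        SimBundle(circle_b, clones_b, truth_b, cfg_b),
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
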