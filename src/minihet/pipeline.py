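"""End-to-end orchestration: assemble, annotate, map, call, summarise.

``run_all`` ties the stages together for a single individual: read (or
simulate) the circle and clone set, map clones to reference coordinates,
call heteroplasmic sites, find inverted repeats, and build the
neighbor-joining clone tree, writing a uniform bundle of outputs
(FASTA + GFF3 + TSV tables + JSON summary + Newick).  Every value in the
summary is also emitted unrounded so the rounded headline numbers remain
reproducible from raw material.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as mio
from .align import ColumnMatrix, map_clones
from .circle import Feature, Minicircle, length_bookkeeping
from .heteroplasmy import HeteroplasmyReport, build_report
from .inverted_repeats import (
    DEFAULT_IR_PARAMS,
    IRScoringParams,
    find_inverted_repeats,
)
from .seq_core import NucSequence, classify_start, subseq_circular
from .tree import distance_matrix_from_columns, neighbor_joining

logger = logging.getLogger("minihet")

__all__ = ["run_all", "heteroplasmy_stage", "ir_stage", "tree_stage"]


def _stage(name: str):
    logger.info("stage %s", name)


def ir_table(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm1_start": h.arm1.start,
                "arm1_end": h.arm1.end,
                "arm1_wraps": h.arm1.wraps,
                "arm2_start": h.arm2.start,
                "arm2_end": h.arm2.end,
                "arm2_wraps": h.arm2.wraps,
                "spacer_len": h.spacer_len,
                "score": h.score,
                "region_span": h.region_span,
            }
            for h in hits
        ]
    )


def site_table(report: HeteroplasmyReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": s.ref_pos,
                "region": s.region,
                "codon_position": s.codon_position if s.codon_position else "",
                "alleles": ",".join(
                    f"{b}x{c}" for b, c in sorted(s.alleles.items())
                ),
            }
            for s in report.sites
        ]
    )


def heteroplasmy_stage(
    circle: Minicircle, clones, outdir: Optional[Path] = None
) -> tuple[ColumnMatrix, HeteroplasmyReport]:
    _stage("map")
    matrix = map_clones(circle, clones)
    _stage("het")
    report = build_report(matrix, circle, clones)
    if outdir is not None:
        site_table(report).to_csv(outdir / "sites.tsv", sep="\t", index=False)
        with open(outdir / "heteroplasmy.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    return matrix, report


def ir_stage(
    circle: Minicircle,
    params: IRScoringParams = DEFAULT_IR_PARAMS,
    outdir: Optional[Path] = None,
):
    _stage("ir")
    hits = find_inverted_repeats(circle.sequence, params)
    if outdir is not None:
        ir_table(hits).to_csv(outdir / "inverted_repeats.tsv", sep="\t", index=False)
    return hits


def tree_stage(matrix: ColumnMatrix, outdir: Optional[Path] = None):
    _stage("tree")
    dm = distance_matrix_from_columns(matrix)
    tree = neighbor_joining(dm)
    if outdir is not None:
        with open(outdir / "clones.nwk", "w") as fh:
            fh.write(tree.newick() + "\n")
    return tree


def run_all(
    circle: Minicircle,
    clones,
    outdir: str | os.PathLike,
    ir_params: IRScoringParams = DEFAULT_IR_PARAMS,
    manifest: Optional[dict] = None,
) -> dict:
    """Run every analysis stage and write the output bundle.

    Returns the summary dictionary that is also written as
    ``summary.json``.  Output is a pure function of the inputs: two runs
    on the same inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _stage("annotate")
    mio.write_fasta(circle.sequence, outdir / "circle.fa")
    mio.write_gff3(circle, outdir / "circle.gff3")
    mio.write_fasta(clones, outdir / "clones.fa")
    bookkeeping = length_bookkeeping(circle)
    gene_seq = subseq_circular(circle.sequence, circle.gene.interval)
    start = classify_start(gene_seq)
    matrix, report = heteroplasmy_stage(circle, clones, outdir)
    hits = ir_stage(circle, ir_params, outdir)
    tree = tree_stage(matrix, outdir)
    summary = {
        "circle_id": circle.sequence.id,
        "circle_length": len(circle),
        "length_bookkeeping": asdict(bookkeeping),
        "start_codon": {"category": start.category, "offset": start.offset,
                        "alternative": start.alternative},
        "heteroplasmy": report.to_dict(),
        "inverted_repeats": ir_table(hits).to_dict(orient="records"),
        "tree_leaves": tree.leaf_labels,
    }
    if manifest is not None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
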