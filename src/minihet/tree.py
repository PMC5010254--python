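"""Neighbor-joining similarity trees among clones.

Distances between clones are uncorrected p-distances (proportion of
differing sites among columns where both clones have an unambiguous
base), which is the natural scale for near-identical clone sequences far
from substitutional saturation.  Trees are built with the Saitou-Nei
neighbor-joining algorithm with a deterministic tie-break (smallest index
pair) and negative branch lengths clamped to zero, and serialised as
Newick with a trifurcating root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .align import ColumnMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "CloneTree",
    "p_distance",
    "neighbor_joining",
    "distance_matrix_from_columns",
]

_BASES = set("ACGT")


def p_distance(a: str, b: str) -> float:
    """Substitutions per comparable site between two gapped rows.

    Columns where either row is a gap, uncovered, or an ambiguity code are
    excluded from both numerator and denominator.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    comparable = 0
    diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _BASES and y in _BASES:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        raise ValueError("no comparable columns between rows")
    return diffs / comparable


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def distance_matrix_from_columns(matrix: ColumnMatrix) -> DistanceMatrix:
    """Pairwise p-distances between clone rows of a reference matrix."""
    rows = [matrix.row_string(i) for i in range(matrix.n_clones)]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(rows[i], rows[j])
    return DistanceMatrix(list(matrix.clone_ids), d)


@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list = field(default_factory=list)  # [(TreeNode, branch_length)]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class CloneTree:
    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label or ""
            inner = ",".join(
                f"{fmt(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"


def neighbor_joining(dm: DistanceMatrix) -> CloneTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    At each step the pair minimising the Q criterion is joined; ties go to
    the smallest (i, j) index pair in the current label order.  Negative
    branch lengths (possible for non-additive input) are clamped to zero
    with a warning.  The unrooted result is returned with a trifurcating
    root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = dm.d.copy()
    nodes = [TreeNode(label) for label in dm.labels]

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative branch length {x:.4g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(
            children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))]
        )
        new_row = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_row[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode(
        children=[
            (nodes[0], clamp(la)),
            (nodes[1], clamp(lb)),
            (nodes[2], clamp(lc)),
        ]
    )
    return CloneTree(root)
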