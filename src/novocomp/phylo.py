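"""Distance phylogenetics on pre-aligned protein sequences.

Pairwise distances use the Poisson correction d = −ln(1 − p), where p is
the proportion of mismatching sites over columns where both sequences are
ungapped (pairwise deletion). Trees are built with Saitou–Nei
neighbor-joining (negative branch estimates clamped to zero, ties broken
by taxon order so results are deterministic), and branch support comes
from bootstrap resampling of alignment columns; supports are mapped onto
the full-data tree as percentages of replicates containing each
bipartition.

Alignment construction (MUSCLE etc.) is out of scope: the module consumes
aligned FASTA. Trees are :class:`skbio.TreeNode` objects, so Newick I/O
and tree comparison come for free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skbio import TreeNode

GAP_CHARS = frozenset("-.")


@dataclass
class AlignmentBlock:
    """A multiple alignment: equal-length rows over taxa."""

    taxon_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxon_ids) != len(self.rows):
            raise ValueError("taxon_ids and rows differ in length")
        if len(self.taxon_ids) < 2:
            raise ValueError("alignment needs >= 2 taxa")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows are not aligned (lengths {sorted(lengths)})")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @classmethod
    def read_fasta(cls, path: str | Path) -> "AlignmentBlock":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def _matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")


@dataclass
class DistanceMatrix:
    taxon_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxon_ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal not zero")


def poisson_distance(row_i: str, row_j: str) -> float:
    """Poisson-corrected distance between two aligned rows.

    p = mismatches / shared ungapped columns (pairwise deletion);
    d = −ln(1 − p). p >= 1 (saturation) raises, as the distance is
    infinite and must be excluded from NJ.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    shared = mismatch = 0
    for a, b in zip(row_i, row_j):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        shared += 1
        if a != b:
            mismatch += 1
    if shared == 0:
        raise ValueError("no shared ungapped column; distance undefined")
    p = mismatch / shared
    if p >= 1.0:
        raise ValueError(f"saturated pair (p={p}); Poisson distance infinite")
    return -math.log(1.0 - p) + 0.0  # normalise -0.0


def distance_matrix(aln: AlignmentBlock) -> DistanceMatrix:
    n = len(aln.taxon_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(aln.rows[i], aln.rows[j])
    return DistanceMatrix(aln.taxon_ids, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Q-matrix joins with deterministic tie-breaks (smallest taxon-id pair),
    branch-length estimates clamped at zero. Returns an unrooted tree
    (trifurcating root) over the taxa.
    """
    if len(dm.taxon_ids) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxon_ids]
    labels = list(dm.taxon_ids)  # tie-break keys: smallest member taxon id
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        # tolerance-based tie detection: mathematically equal Q values can
        # differ in the last ulp, which would defeat the taxon-order tie-break
        best: Optional[tuple] = None
        best_q = math.inf
        scale = max(1.0, float(np.abs(d).max()))
        tol = 1e-10 * scale
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                label = (min(labels[i], labels[j]), max(labels[i], labels[j]))
                if q < best_q - tol or (q <= best_q + tol and (best is None or label < best[0])):
                    best_q = min(q, best_q)
                    best = (label, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        d = d2

    # connect the last three nodes to a central trifurcation:
    # l_a = (d_ab + d_ac - d_bc)/2, cyclically
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return TreeNode(children=[a, b, c])


def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalised to the side not containing
    the alphabetically first taxon (unrooted comparison)."""
    anchor = min(taxa)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        splits.add(side)
    return splits


def _pair_masks(aln: AlignmentBlock) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    m = aln._matrix()
    gap = np.isin(m, list(GAP_CHARS))
    n = len(aln.taxon_ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.array([~(gap[i] | gap[j]) for i, j in pairs])
    mism = np.array([(m[i] != m[j]) for i, j in pairs]) & valid
    return valid, mism, pairs


def bootstrap(
    aln: AlignmentBlock,
    replicates: int = 1000,
    seed: int = 0,
    tree: Optional[TreeNode] = None,
) -> TreeNode:
    """Bootstrap branch support by resampling alignment columns.

    Rebuilds Poisson distances + NJ per replicate; each internal node of
    the full-data tree (or a supplied ``tree``) is annotated with the
    percentage of replicates containing its bipartition (``node.name``,
    integer string; full precision on ``node.bootstrap``). Replicates where a pair
    saturates or shares no column are skipped and excluded from the
    denominator.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    taxa = frozenset(aln.taxon_ids)
    ref = tree if tree is not None else nj_tree(distance_matrix(aln))
    ref_splits = _bipartitions(ref, taxa)
    counts = {s: 0 for s in ref_splits}
    valid, mism, pairs = _pair_masks(aln)
    n = len(aln.taxon_ids)
    used = 0
    for _ in range(replicates):
        idx = rng.integers(0, aln.n_cols, size=aln.n_cols)
        shared = valid[:, idx].sum(axis=1)
        bad = mism[:, idx].sum(axis=1)
        if np.any(shared == 0) or np.any(bad >= shared):
            continue
        p = bad / shared
        dvals = -np.log(1.0 - p) + 0.0
        d = np.zeros((n, n))
        for (i, j), v in zip(pairs, dvals):
            d[i, j] = d[j, i] = v
        rep_tree = nj_tree(DistanceMatrix(aln.taxon_ids, d))
        rep_splits = _bipartitions(rep_tree, taxa)
        used += 1
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates degenerate")
    for node in ref.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        canonical = taxa - side if min(taxa) in side else side
        support = 100.0 * counts[canonical] / used
        node.name = str(int(round(support)))
        node.bootstrap = support  # full precision; .support would alter newick output
    return ref
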