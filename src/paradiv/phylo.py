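"""Protein distance estimation, BIONJ tree construction, bootstrap support.

Distances are p-distances under pairwise deletion (columns with a gap or an
``X`` in either row are skipped), optionally Poisson-corrected
(d = -ln(1 - p)). Trees are built with the BIONJ agglomeration (Gascuel 1997,
Mol Biol Evol 14:685-695): standard neighbor-joining pair selection and
branch-length estimates, but a variance-weighted reduction step. On additive
matrices the algorithm recovers the generating tree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import GAP, AlignedSet
from .tree import PhyloTree, TreeNode

MISSING = {GAP, "X"}


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    model: str = "observed"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise DistanceError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise DistanceError("distance matrix must have a zero diagonal")
        if not np.isfinite(self.d).all():
            raise DistanceError("distance matrix contains non-finite entries")
        if (self.d < 0).any():
            raise DistanceError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, model: str = "observed") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], d=df.to_numpy(), model=model)


def p_distance(msa: AlignedSet, i: str, j: str) -> float:
    """Proportion of differing residues over pairwise-comparable columns."""
    row_i, row_j = msa.rows[i], msa.rows[j]
    compared = mismatches = 0
    for a, b in zip(row_i, row_j):
        if a in MISSING or b in MISSING:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise DistanceError(f"no comparable columns between {i!r} and {j!r}")
    return mismatches / compared


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p)."""
    if not 0 <= p < 1:
        raise DistanceError(f"p-distance {p} outside [0, 1)")
    return -math.log1p(-p)


def distance_matrix(msa: AlignedSet, model: str = "poisson") -> DistanceMatrix:
    """All pairwise distances under the chosen model (observed | poisson)."""
    if model not in ("observed", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = msa.ids
    n = len(ids)
    arr = np.array([list(msa.rows[rid]) for rid in ids])
    valid = ~np.isin(arr, sorted(MISSING))
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            both = valid[a] & valid[b]
            compared = int(both.sum())
            if compared == 0:
                raise DistanceError(f"no comparable columns between {ids[a]!r} and {ids[b]!r}")
            p = float(((arr[a] != arr[b]) & both).sum()) / compared
            d[a, b] = d[b, a] = poisson_correct(p) if model == "poisson" else p
    return DistanceMatrix(labels=ids, d=d, model=model)


def build_bionj(dm: DistanceMatrix) -> PhyloTree:
    """BIONJ agglomeration; returns an unrooted tree as a trifurcating root.

    Ties in the Q criterion break on the smallest (row, col) index pair in the
    current cluster ordering; negative branch-length estimates are clamped to
    zero with the deficit transferred to the sister branch, preserving the
    local path length.
    """
    n = len(dm.labels)
    if n < 3:
        raise DistanceError("BIONJ needs at least 3 taxa")
    d = dm.d.copy()
    v = dm.d.copy()  # pair variances; proportional to distances initially
    nodes: list[TreeNode] = [TreeNode(lbl) for lbl in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # Q criterion; select minimal pair with deterministic tie-break
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        b_i = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        b_j = d[i, j] - b_i
        b_i, b_j = _clamp_pair(b_i, b_j)

        if v[i, j] > 0:
            lam = 0.5 + sum(
                v[j, k] - v[i, k] for k in range(m) if k not in (i, j)
            ) / (2 * (m - 2) * v[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        new = TreeNode(None)
        new.add_child(nodes[i]).length = b_i
        new.add_child(nodes[j]).length = b_j

        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros(len(keep) + 1)
        v_new = np.zeros(len(keep) + 1)
        for idx, k in enumerate(keep):
            d_new[idx] = lam * (d[i, k] - b_i) + (1 - lam) * (d[j, k] - b_j)
            v_new[idx] = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * v[i, j]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[:-1]])
        d = np.column_stack([d, d_new])
        v = np.vstack([v[np.ix_(keep, keep)], v_new[:-1]])
        v = np.column_stack([v, v_new])
        nodes = [nodes[k] for k in keep] + [new]

    # exact 3-taxon resolution
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(None)
    for node, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(node).length = max(0.0, length)
    return PhyloTree(root)


def _clamp_pair(b_i: float, b_j: float) -> tuple[float, float]:
    if b_i < 0:
        b_j += b_i
        b_i = 0.0
    if b_j < 0:
        b_i = max(0.0, b_i + b_j)
        b_j = 0.0
    return b_i, b_j


def bootstrap_support(
    msa: AlignedSet,
    model: str = "poisson",
    n_reps: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Column-bootstrap supports on the point-estimate BIONJ tree.

    Columns are resampled with replacement (codon alignments are resampled in
    whole codons); each replicate tree's leaf bipartitions are tallied and the
    percentage containing each point-tree bipartition is written to that
    edge's support field.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = build_bionj(distance_matrix(msa, model))
    unit = 3 if msa.alphabet_kind == "codon" else 1
    n_units = msa.ncols // unit
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {split: 0 for split in point.bipartitions()}
    for _ in range(n_reps):
        draw = rng.integers(n_units, size=n_units)
        cols = [u * unit + off + 1 for u in draw for off in range(unit)]
        rep = build_bionj(distance_matrix(msa.take_columns(cols), model))
        rep_splits = rep.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    leafset = frozenset(point.leaf_names())

    def annotate(node: TreeNode, below: frozenset) -> None:
        if 1 < len(below) < len(leafset) - 1:
            split = min(below, leafset - below, key=lambda s: (len(s), sorted(s)))
            if split in counts:
                node.support = 100.0 * counts[split] / n_reps

    def walk(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not point.root:
            annotate(node, below)
        return below

    walk(point.root)
    return point
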