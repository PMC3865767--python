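"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from paradiv.tree import PhyloTree, TreeNode

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Independent brute-force oracle for local alignment
# ---------------------------------------------------------------------------

def global_affine_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Plain three-state global affine DP (Gotoh), written independently of the
    production aligner. Opening a length-1 gap costs gap_open + gap_extend."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open - gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def brute_force_local_score(a: str, b: str, sub, gap_open: float,
                            gap_extend: float) -> float:
    """Best local alignment score = max over all nonempty substring pairs of
    the global affine score (exhaustive; only usable for short strings)."""
    best = float("-inf")
    for i0, i1 in itertools.combinations(range(len(a) + 1), 2):
        for j0, j1 in itertools.combinations(range(len(b) + 1), 2):
            best = max(
                best,
                global_affine_score(a[i0:i1], b[j0:j1], sub, gap_open, gap_extend),
            )
    return best


def local_affine_score_oracle(a: str, b: str, sub, gap_open: float,
                              gap_extend: float) -> float:
    """Independent Smith-Waterman affine DP over all local alignments.

    Written from the recurrences directly (no shared code with the production
    path); agrees with the substring-pair enumeration oracle, which is used to
    validate it on tiny inputs.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = neg
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open - gap_extend,
            )
            best = max(best, M[i][j])
    return best


# ---------------------------------------------------------------------------
# Independent exhaustive oracle for parsimony
# ---------------------------------------------------------------------------

def exhaustive_parsimony_score(tree: PhyloTree, leaf_seqs: dict[str, str]) -> int:
    """Minimum substitution count over ALL internal labelings, by enumeration.

    Per nucleotide column, tries every assignment of A/C/G/T to every internal
    node and counts changes along edges; leaf gaps match any state for free.
    """
    internals = [n for n in tree.postorder() if not n.is_leaf]
    edges = []
    for node in tree.postorder():
        if node.parent is not None:
            edges.append((node.parent, node))
    ncols = len(next(iter(leaf_seqs.values())))
    total = 0
    for col in range(ncols):
        leaf_state = {name: seq[col] for name, seq in leaf_seqs.items()}
        best = None
        for assignment in itertools.product("ACGT", repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assignment)}
            cost = 0
            for parent, child in edges:
                ps = state[id(parent)]
                cs = leaf_state[child.name] if child.is_leaf else state[id(child)]
                if cs == "-":
                    continue  # missing data imposes no constraint
                if ps != cs:
                    cost += 1
            if best is None or cost < best:
                best = cost
                if best == 0:
                    break
        total += best
    return total


# ---------------------------------------------------------------------------
# Constructed alignment fixture for block extraction
# ---------------------------------------------------------------------------

def block_fixture_msa():
    """Eight rows; columns 5-14 are an invariant core, flank columns carry
    eight distinct residues each (information content ~1.32 bits, below the
    2-bit threshold) and two gapped positions.
    """
    from paradiv.seqio import AlignedSet

    core = "DTGSSNFAVG"
    pools = ["ACDEFGHI", "KLMNPQRS", "TVWYACDE", "FGHIKLMN"]
    rows = {}
    for row in range(8):
        left = "".join(pools[k][(row + k) % 8] for k in range(4))
        right = "".join(pools[3 - k][(row + 3 + k) % 8] for k in range(4))
        rows[f"r{row}"] = left + core + right
    # gapped context in one row
    r7 = list(rows["r7"])
    r7[0] = "-"
    r7[-1] = "-"
    rows["r7"] = "".join(r7)
    return AlignedSet(rows)


# ---------------------------------------------------------------------------
# Random tree helpers
# ---------------------------------------------------------------------------

def random_unrooted_tree(n_leaves: int, rng: np.random.Generator,
                         min_len: float = 0.1, max_len: float = 1.0) -> PhyloTree:
    """Random topology with branch lengths bounded away from zero, returned
    with a trifurcating root (the unrooted convention)."""
    nodes = [TreeNode(f"L{i}", float(rng.uniform(min_len, max_len)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(None, float(rng.uniform(min_len, max_len)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode(None)
    for node in nodes:
        root.add_child(node)
    return PhyloTree(root)


def random_binary_rooted_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    nodes = [TreeNode(f"L{i}", float(rng.uniform(0.1, 1.0))) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(None, float(rng.uniform(0.1, 1.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    nodes[0].length = 0.0
    return PhyloTree(nodes[0])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130917)


@pytest.fixture(scope="session")
def blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


@pytest.fixture(scope="session")
def bace_decoys():
    from paradiv.simulate import decorate_architecture

    return [decorate_architecture("bace-like", 4000 + k) for k in range(20)]


@pytest.fixture(scope="session")
def cathepsin_decoys():
    from paradiv.simulate import decorate_architecture

    return [decorate_architecture("cathepsin-like", 5000 + k) for k in range(20)]


@pytest.fixture(scope="session")
def triage_references():
    from paradiv.simulate import decorate_architecture

    ref_bace = decorate_architecture("bace-like", 1000)
    ref_caths = [decorate_architecture("cathepsin-like", 2000 + k) for k in range(3)]
    return ref_bace, ref_caths
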