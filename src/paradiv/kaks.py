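"""Counting-based Ka/Ks over whole coding regions and partitions.

Two estimators are provided. ``ng86`` is Nei-Gojobori (1986) pairwise
counting averaged over all sequence pairs: expected synonymous (S) and
nonsynonymous (N) site counts per codon come from classifying each of the
nine single-nucleotide neighbors against the standard code (changes into stop
codons are dropped without renormalisation, so s + n <= 3 per codon);
observed differences in multi-hit codons are averaged over all orderings of
single steps with stop-traversing paths excluded; proportions are
Jukes-Cantor corrected, k = -3/4 ln(1 - 4p/3). ``slac`` is a SLAC-style
tree-based variant: ancestral codons are reconstructed with Fitch parsimony
on a supplied (or BIONJ) tree, per-branch differences are summed over the
whole tree, and the ratio is formed from tree-total rates. Both methods can
be restricted to partitions (domains/exons) given on a reference sequence.

Ratios with Ks = 0 are reported as undefined via a flag, never as infinity:
a 0.000 in a results table must mean Ka = 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .seqio import (
    CODON_TO_AA,
    GAP,
    STOP_CODONS,
    AlignedSet,
    CodingSequence,
    PartitionTable,
    translate,
)
from .tree import PhyloTree, TreeNode

SATURATION_P = 0.75  # JC correction is undefined at or beyond this


class KaKsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Codon alignment construction
# ---------------------------------------------------------------------------

def back_translate(
    protein_msa: AlignedSet, cds_by_id: dict[str, CodingSequence]
) -> AlignedSet:
    """Expand a protein alignment to codons using each row's source CDS.

    Every protein row must translate exactly from its CDS; a '-' residue
    expands to '---'. The first discordant residue is named on error.
    """
    rows: dict[str, str] = {}
    for rid, prow in protein_msa.rows.items():
        if rid not in cds_by_id:
            raise KaKsError(f"no CDS supplied for {rid!r}")
        cds = cds_by_id[rid]
        protein = translate(cds).residues
        ungapped = prow.replace(GAP, "")
        if len(protein) != len(ungapped):
            raise KaKsError(
                f"{rid!r}: CDS translates to {len(protein)} residues but the "
                f"alignment row has {len(ungapped)}"
            )
        for pos, (x, y) in enumerate(zip(protein, ungapped), start=1):
            if x != y:
                raise KaKsError(
                    f"{rid!r}: translation mismatch at residue {pos}: "
                    f"CDS gives {x!r}, alignment row has {y!r}"
                )
        codons = cds.codons()
        out = []
        k = 0
        for ch in prow:
            if ch == GAP:
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        rows[rid] = "".join(out)
    return AlignedSet(rows, alphabet_kind="codon")


# ---------------------------------------------------------------------------
# NG86 counting machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) site counts of one sense codon.

    Each of the nine single-nucleotide neighbors counts 1/3 of a site toward
    the class of its effect; neighbors that are stop codons are dropped.
    """
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        raise KaKsError(f"{codon!r} is not a sense codon")
    syn = non = 0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            other = codon[:pos] + nt + codon[pos + 1 :]
            if other in STOP_CODONS:
                continue
            if CODON_TO_AA[other] == aa:
                syn += 1
            else:
                non += 1
    return syn / 3.0, non / 3.0


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Observed (synonymous, nonsynonymous) differences between two sense codons.

    Codons differing at 2-3 positions are averaged over all orderings of
    single steps; paths passing through a stop codon are excluded. Returns
    None when every path is stop-blocked (the codon pair is uncountable).
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in CODON_TO_AA:
            raise KaKsError(f"{c!r} is not a sense codon")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    path_counts = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok:
            path_counts.append((sd, nd))
    if not path_counts:
        return None
    sd = sum(p[0] for p in path_counts) / len(path_counts)
    nd = sum(p[1] for p in path_counts) / len(path_counts)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction, k = -3/4 ln(1 - 4p/3)."""
    if p >= SATURATION_P:
        raise KaKsError(f"proportion {p} saturated (>= {SATURATION_P})")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ka: float | None
    ks: float | None
    ratio: float | None
    partition: str = "All"
    method: str = "ng86-mean-pairwise"
    flags: list[str] = field(default_factory=list)
    n_codons: int = 0

    @property
    def ps(self) -> float | None:
        return self.sd / self.s_sites if self.s_sites > 0 else None

    @property
    def pn(self) -> float | None:
        return self.nd / self.n_sites if self.n_sites > 0 else None

    def to_row(self) -> dict:
        return {
            "partition": self.partition,
            "method": self.method,
            "n_codons": self.n_codons,
            "S_sites": round(self.s_sites, 3),
            "N_sites": round(self.n_sites, 3),
            "Sd": round(self.sd, 3),
            "Nd": round(self.nd, 3),
            "Ks": None if self.ks is None else round(self.ks, 5),
            "Ka": None if self.ka is None else round(self.ka, 5),
            "KaKs": None if self.ratio is None else round(self.ratio, 5),
            "flags": ";".join(self.flags),
        }


def _codon_columns(row: str) -> list[str]:
    return [row[i : i + 3] for i in range(0, len(row), 3)]


def ng86_pair(row_a: str, row_b: str, partition: str = "All") -> KaKsResult:
    """NG86 counting between two aligned codon rows.

    Codon columns containing a gap in either row are skipped pairwise;
    stop-blocked multi-hit codons are skipped with a flag.
    """
    if len(row_a) != len(row_b):
        raise KaKsError("rows differ in length")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    flags: list[str] = []
    n_codons = 0
    for ca, cb in zip(_codon_columns(row_a), _codon_columns(row_b)):
        if GAP in ca or GAP in cb:
            continue
        n_codons += 1
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        s_a += sa; n_a += na; s_b += sb; n_b += nb
        counts = codon_pair_differences(ca, cb)
        if counts is None:
            if "stop_blocked_codon_skipped" not in flags:
                flags.append("stop_blocked_codon_skipped")
            continue
        sd += counts[0]
        nd += counts[1]
    if n_codons == 0:
        raise KaKsError("no comparable codon columns")
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ka = ks = ratio = None
    if ps >= SATURATION_P or pn >= SATURATION_P:
        flags.append("saturated")
    else:
        ks = jukes_cantor(ps)
        ka = jukes_cantor(pn)
        if ks > 0:
            ratio = ka / ks
        else:
            flags.append("ks_zero_ratio_undefined")
    return KaKsResult(
        s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
        ka=ka, ks=ks, ratio=ratio, partition=partition,
        method="ng86-pair", flags=flags, n_codons=n_codons,
    )


def dataset_kaks_ng86(
    codon_msa: AlignedSet, partition: str = "All"
) -> tuple[KaKsResult, pd.DataFrame]:
    """Mean-over-pairs NG86: Ka and Ks averaged over all unordered pairs,
    ratio = mean Ka / mean Ks. Returns the aggregate and the per-pair table."""
    ids = codon_msa.ids
    per_pair = []
    kas, kss = [], []
    flags: list[str] = []
    agg_s = agg_n = agg_sd = agg_nd = 0.0
    n_codons = 0
    for a, b in itertools.combinations(ids, 2):
        res = ng86_pair(codon_msa.rows[a], codon_msa.rows[b], partition)
        per_pair.append({"pair": f"{a}|{b}", **res.to_row()})
        agg_s += res.s_sites; agg_n += res.n_sites
        agg_sd += res.sd; agg_nd += res.nd
        n_codons = max(n_codons, res.n_codons)
        for f in res.flags:
            if f not in flags:
                flags.append(f)
        if res.ka is not None:
            kas.append(res.ka)
            kss.append(res.ks)
    n_pairs = len(per_pair)
    mean_ka = sum(kas) / len(kas) if kas else None
    mean_ks = sum(kss) / len(kss) if kss else None
    ratio = None
    if mean_ka is not None and mean_ks and mean_ks > 0:
        ratio = mean_ka / mean_ks
    elif mean_ks == 0 and "ks_zero_ratio_undefined" not in flags:
        flags.append("ks_zero_ratio_undefined")
    result = KaKsResult(
        s_sites=agg_s / n_pairs, n_sites=agg_n / n_pairs,
        sd=agg_sd / n_pairs, nd=agg_nd / n_pairs,
        ka=mean_ka, ks=mean_ks, ratio=ratio,
        partition=partition, method="ng86-mean-pairwise",
        flags=flags, n_codons=n_codons,
    )
    return result, pd.DataFrame(per_pair)


# ---------------------------------------------------------------------------
# Fitch parsimony + SLAC-style counting
# ---------------------------------------------------------------------------

_NT = "ACGT"
_FULL = frozenset(_NT)


def _binarise(tree: PhyloTree) -> PhyloTree:
    """Resolve multifurcations arbitrarily with zero-length edges (parsimony-
    neutral), so Fitch runs on a binary tree."""
    work = tree.copy()
    for node in list(work.postorder()):
        while len(node.children) > 2:
            a = node.children.pop()
            b = node.children.pop()
            join = TreeNode(None, 0.0)
            join.add_child(a)
            join.add_child(b)
            node.add_child(join)
    return work


def fitch_ancestral(
    tree: PhyloTree, codon_msa: AlignedSet
) -> tuple[dict[int, str], PhyloTree, int]:
    """Fitch parsimony ancestral codons for every internal node.

    Runs per nucleotide column (gaps at leaves are missing data and impose no
    constraint). Among the minimum-change assignments, each internal codon is
    resolved by preferring non-stop codons, then the fewest nonsynonymous
    changes on the edge to its parent, then lexicographic order.

    Returns ({node id: codon string}, the binarised working tree, and the
    nucleotide-level parsimony score).
    """
    work = _binarise(tree)
    leaves = {n.name for n in work.leaves()}
    missing = leaves - set(codon_msa.ids)
    if missing:
        raise KaKsError(f"tree leaves missing from alignment: {sorted(missing)}")
    ncols = codon_msa.ncols
    score = 0

    # bottom-up state sets per node per nucleotide column
    sets: dict[int, list[frozenset[str]]] = {}
    for node in work.postorder():
        if node.is_leaf:
            row = codon_msa.rows[node.name]
            sets[id(node)] = [
                _FULL if row[c] == GAP else frozenset(row[c]) for c in range(ncols)
            ]
            continue
        kids = [sets[id(c)] for c in node.children]
        own: list[frozenset[str]] = []
        for c in range(ncols):
            inter = kids[0][c]
            for ks in kids[1:]:
                inter = inter & ks[c]
            if inter:
                own.append(inter)
            else:
                union = kids[0][c]
                for ks in kids[1:]:
                    union = union | ks[c]
                own.append(union)
                score += 1
        sets[id(node)] = own

    # top-down resolution, codon by codon
    assigned: dict[int, str] = {}
    for node in work.preorder():
        if node.is_leaf:
            continue
        node_sets = sets[id(node)]
        parent_codon = None if node.parent is None else assigned[id(node.parent)]
        codons = []
        for ci in range(ncols // 3):
            pc = None if parent_codon is None else parent_codon[3 * ci : 3 * ci + 3]
            cands_per_pos = []
            for off in range(3):
                s = node_sets[3 * ci + off]
                if pc is not None and pc[off] in s:
                    cands_per_pos.append([pc[off]])
                else:
                    cands_per_pos.append(sorted(s))
            candidates = ["".join(t) for t in itertools.product(*cands_per_pos)]
            non_stop = [c for c in candidates if c not in STOP_CODONS]
            pool = non_stop or candidates
            best = min(pool, key=lambda cand: (_nonsyn_vs(pc, cand), cand))
            codons.append(best)
        codon_str = "".join(codons)
        assigned[id(node)] = codon_str

    return assigned, work, score


def _nonsyn_vs(parent_codon: str | None, cand: str) -> float:
    if parent_codon is None or parent_codon in STOP_CODONS or cand in STOP_CODONS:
        return 0.0
    counts = codon_pair_differences(parent_codon, cand) if (
        parent_codon in CODON_TO_AA and cand in CODON_TO_AA
    ) else None
    if counts is None:
        return sum(1 for a, b in zip(parent_codon, cand) if a != b)
    return counts[1]


def dataset_kaks_slac(
    tree: PhyloTree, codon_msa: AlignedSet, partition: str = "All"
) -> KaKsResult:
    """SLAC-style tree counting: per-branch differences between Fitch-assigned
    parent and child codons summed over the tree; site counts are the mean of
    the per-node (leaves + ancestors) summed NG86 site counts; the ratio is
    (sum Nd / N_sites) / (sum Sd / S_sites)."""
    ancestors, work, _ = fitch_ancestral(tree, codon_msa)

    def node_codons(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return _codon_columns(codon_msa.rows[node.name])
        return _codon_columns(ancestors[id(node)])

    sum_sd = sum_nd = 0.0
    flags: list[str] = []
    for node in work.postorder():
        if node.parent is None:
            continue
        child_c = node_codons(node)
        parent_c = node_codons(node.parent)
        for ca, cb in zip(parent_c, child_c):
            if GAP in ca or GAP in cb:
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            counts = codon_pair_differences(ca, cb)
            if counts is None:
                if "stop_blocked_codon_skipped" not in flags:
                    flags.append("stop_blocked_codon_skipped")
                continue
            sum_sd += counts[0]
            sum_nd += counts[1]

    # site counts averaged over every node's sequence
    totals = []
    n_codons = 0
    for node in work.postorder():
        s_tot = n_tot = 0.0
        count = 0
        for codon in node_codons(node):
            if GAP in codon or codon in STOP_CODONS:
                continue
            s, n = ng86_sites(codon)
            s_tot += s
            n_tot += n
            count += 1
        totals.append((s_tot, n_tot))
        n_codons = max(n_codons, count)
    s_sites = sum(t[0] for t in totals) / len(totals)
    n_sites = sum(t[1] for t in totals) / len(totals)

    ka = sum_nd / n_sites if n_sites > 0 else None
    ks = sum_sd / s_sites if s_sites > 0 else None
    if ks and ks > 0 and ka is not None:
        ratio = ka / ks
    else:
        ratio = None
        flags.append("ks_zero_ratio_undefined")
    return KaKsResult(
        s_sites=s_sites, n_sites=n_sites, sd=sum_sd, nd=sum_nd,
        ka=ka, ks=ks, ratio=ratio, partition=partition,
        method="slac-like", flags=flags, n_codons=n_codons,
    )


# ---------------------------------------------------------------------------
# Partitioned analysis
# ---------------------------------------------------------------------------

def _partition_columns(
    codon_msa: AlignedSet, reference_id: str, start_aa: int, end_aa: int
) -> list[int]:
    """1-based codon-alignment nucleotide columns for a residue span on the
    (possibly gapped) reference row."""
    if reference_id not in codon_msa.rows:
        raise KaKsError(f"reference {reference_id!r} not in alignment")
    ref_codons = _codon_columns(codon_msa.rows[reference_id])
    ref_len = sum(1 for c in ref_codons if GAP not in c)
    if end_aa > ref_len:
        raise KaKsError(
            f"partition end {end_aa} beyond reference length {ref_len}"
        )
    cols: list[int] = []
    aa = 0
    for ci, codon in enumerate(ref_codons):
        if GAP in codon:
            continue
        aa += 1
        if start_aa <= aa <= end_aa:
            cols.extend(range(3 * ci + 1, 3 * ci + 4))
    return cols


def partition_kaks(
    codon_msa: AlignedSet,
    partitions: PartitionTable,
    reference_id: str,
    method: str = "both",
    tree: PhyloTree | None = None,
) -> pd.DataFrame:
    """Ka/Ks per partition plus a whole-alignment "All" row, as a tidy table.

    ``method`` is ng86 | slac | both; slac requires (or builds implicitly —
    callers should pass one for reproducibility) a tree whose leaves are the
    alignment rows.
    """
    if method not in ("ng86", "slac", "both"):
        raise ValueError(f"unknown method {method!r}")
    methods = ["ng86", "slac"] if method == "both" else [method]
    if "slac" in methods and tree is None:
        from .phylo import build_bionj, distance_matrix
        from .simulate import protein_alignment

        tree = build_bionj(distance_matrix(protein_alignment(codon_msa), "poisson"))

    spans: list[tuple[str, int | None, int | None]] = [("All", None, None)]
    spans += [(p.name, p.start_aa, p.end_aa) for p in partitions]

    rows = []
    for name, start, end in spans:
        if start is None:
            sub = codon_msa
        else:
            cols = _partition_columns(codon_msa, reference_id, start, end)
            if not cols:
                raise KaKsError(f"partition {name!r} maps to no alignment columns")
            sub = codon_msa.take_columns(cols)
        for m in methods:
            if m == "ng86":
                res, _ = dataset_kaks_ng86(sub, partition=name)
            else:
                res = dataset_kaks_slac(tree, sub, partition=name)
            row = res.to_row()
            row["start_aa"], row["end_aa"] = start, end
            rows.append(row)
    return pd.DataFrame(rows)
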