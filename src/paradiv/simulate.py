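"""Synthetic duplicated gene families with known truth.

The generator emulates the situation the downstream analyses are built for:
a species tree, one duplication at its root producing paralog clades A and B,
a clade-specific rate multiplier on clade B (a BACE2-like acceleration), and
codon evolution under per-partition omega (dN/dS) with a transition/
transversion ratio kappa. Protein architectures (signal peptide, aspartyl
active-site motifs, C-terminal transmembrane stretch, ~100-residue length
difference) are generated separately as classification decoys.

Branch lengths are calibrated so one unit equals one expected nucleotide
substitution per nucleotide site at the root codon composition, which makes
simulated divergences directly comparable to the protein-distance estimators.
States are propagated with exact transition probabilities (matrix exponential
of the 61-state generator per branch and omega class); rates into stop codons
are zero, so no simulated lineage ever passes through a stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.linalg import expm

from .seqio import (
    CODON_TO_AA,
    SENSE_CODONS,
    AlignedSet,
    Sequence,
)
from .tree import PhyloTree, TreeNode

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_N_CODONS = len(SENSE_CODONS)  # 61


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def _neighbor_table() -> list[tuple[int, int, bool, bool]]:
    """All single-nucleotide sense-to-sense changes.

    Returns (i, j, is_transition, is_synonymous) tuples.
    """
    out = []
    for ci, codon in enumerate(SENSE_CODONS):
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                other = codon[:pos] + nt + codon[pos + 1 :]
                cj = _CODON_INDEX.get(other)
                if cj is None:  # stop codon: rate zero
                    continue
                out.append(
                    (
                        ci,
                        cj,
                        _is_transition(codon[pos], nt),
                        CODON_TO_AA[codon] == CODON_TO_AA[other],
                    )
                )
    return out


_NEIGHBORS = _neighbor_table()


def codon_rate_matrix(kappa: float, omega: float, root_freqs: np.ndarray) -> np.ndarray:
    """61x61 generator: accepted single-nucleotide changes at relative rate 1
    (synonymous) or omega (nonsynonymous), transitions weighted kappa.

    Scaled so the mean total rate at ``root_freqs`` equals 3 substitutions per
    codon (= 1 per nucleotide site) per unit branch length.
    """
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be non-negative")
    q = np.zeros((_N_CODONS, _N_CODONS))
    for i, j, is_ts, is_syn in _NEIGHBORS:
        rate = (kappa if is_ts else 1.0) * (1.0 if is_syn else omega)
        q[i, j] = rate
    np.fill_diagonal(q, 0.0)
    q[np.diag_indices_from(q)] = -q.sum(axis=1)
    mu = float(root_freqs @ (-np.diag(q)))
    if mu <= 0:
        raise ValueError("degenerate codon process (zero total rate)")
    return q * (3.0 / mu)


@dataclass
class SimParams:
    """Generator settings; the defaults are the package's study conditions.

    omega_by_partition entries are (name, start_codon, end_codon, omega) with
    1-based inclusive codon coordinates that must tile 1..codon_length.
    """

    n_species: int = 10
    tree_shape: Literal["yule"] | str = "yule"  # or a fixed newick string
    total_height: float = 0.1
    rate_multiplier_r: float = 2.0
    kappa: float = 2.0
    omega_by_partition: list[tuple[str, int, int, float]] | None = None
    codon_length: int = 500
    codon_frequencies: np.ndarray | None = None  # length 61, sums to 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.rate_multiplier_r <= 0:
            raise ValueError("rate_multiplier_r must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.codon_length < 1:
            raise ValueError("codon_length must be >= 1")
        if self.omega_by_partition is None:
            self.omega_by_partition = [("All", 1, self.codon_length, 0.1)]
        spans = sorted(self.omega_by_partition, key=lambda p: p[1])
        cursor = 1
        for name, start, end, omega in spans:
            if omega < 0:
                raise ValueError(f"omega must be >= 0 in partition {name!r}")
            if start != cursor:
                raise ValueError(
                    f"omega partitions must tile 1..codon_length; gap/overlap at {start}"
                )
            if end < start:
                raise ValueError(f"partition {name!r}: end < start")
            cursor = end + 1
        if cursor != self.codon_length + 1:
            raise ValueError("omega partitions must end at codon_length")
        if self.codon_frequencies is not None:
            f = np.asarray(self.codon_frequencies, dtype=float)
            if f.shape != (_N_CODONS,) or not np.isclose(f.sum(), 1.0) or (f < 0).any():
                raise ValueError("codon_frequencies must be a length-61 simplex vector")
            self.codon_frequencies = f

    def root_freqs(self) -> np.ndarray:
        if self.codon_frequencies is None:
            return np.full(_N_CODONS, 1.0 / _N_CODONS)
        return self.codon_frequencies


@dataclass
class SimTruth:
    """Truth channel for parameter-recovery tests."""

    params: SimParams
    species_tree: PhyloTree
    gene_tree: PhyloTree
    alignment: AlignedSet  # codon alignment, no indels
    labels: dict[str, tuple[str, str]]  # id -> (species, clade)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_species_tree(
    n_species: int,
    seed: int | np.random.Generator,
    total_height: float = 0.1,
) -> PhyloTree:
    """Ultrametric Yule tree: exponential waiting times between speciations,
    a uniformly chosen lineage splits at each event, and branch lengths are
    rescaled so every root-to-tip path equals ``total_height``.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = _as_rng(seed)
    # The root splits at time 0 into two lineages; thereafter, with k lineages
    # the next speciation arrives after Exp(k) and hits a uniform lineage.
    root = TreeNode("root")
    first, second = TreeNode(None), TreeNode(None)
    root.add_child(first)
    root.add_child(second)
    active: list[tuple[TreeNode, float]] = [(first, 0.0), (second, 0.0)]
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.length = t - born
        left, right = TreeNode(None), TreeNode(None)
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    # final stretch with n lineages, then the present day
    t += rng.exponential(1.0 / n_species)
    for i, (node, born) in enumerate(active):
        node.length = t - born
    # name leaves in a stable left-to-right order
    counter = [0]

    def name_leaves(node: TreeNode) -> None:
        if not node.children:
            counter[0] += 1
            node.name = f"sp{counter[0]}"
        for child in node.children:
            name_leaves(child)

    name_leaves(root)
    scale = total_height / t
    return PhyloTree(root).copy(scale=lambda x: x * scale)


def graft_duplication(
    species_tree: PhyloTree, r: float, stem_frac: float = 0.5
) -> PhyloTree:
    """Duplication preceding the radiation: two copies of the species tree
    under a new root, clade-B branch lengths multiplied by r, leaf labels
    suffixed _A/_B.

    Each copy hangs from a stem branch of ``stem_frac`` times the species-tree
    height (scaled by r on the B side), representing the post-duplication
    interval before the radiation; within-clade distances never traverse the
    stems, so clade-internal statistics are independent of ``stem_frac``.
    """
    if r <= 0:
        raise ValueError("rate multiplier r must be > 0")
    height = max(species_tree.root_to_tip_depths().values())
    copy_a = species_tree.copy()
    copy_b = species_tree.copy(scale=lambda x: x * r)
    copy_a.root.length = stem_frac * height
    copy_b.root.length = stem_frac * height * r
    copy_a.relabel_leaves(lambda name: f"{name}_A")
    copy_b.relabel_leaves(lambda name: f"{name}_B")
    copy_a.root.name, copy_b.root.name = "cladeA", "cladeB"
    root = TreeNode("dup_root")
    root.add_child(copy_a.root)
    root.add_child(copy_b.root)
    return PhyloTree(root)


def _site_omega_classes(params: SimParams) -> tuple[np.ndarray, list[float]]:
    """Map each codon site (0-based) to an index into the distinct-omega list."""
    omegas: list[float] = []
    site_class = np.zeros(params.codon_length, dtype=int)
    for name, start, end, omega in params.omega_by_partition:
        if omega not in omegas:
            omegas.append(omega)
        site_class[start - 1 : end] = omegas.index(omega)
    return site_class, omegas


def simulate_codon_msa(
    gene_tree: PhyloTree,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[AlignedSet, SimTruth]:
    """Evolve codon states down ``gene_tree`` under the partitioned process.

    No indels are generated, so alignment columns are the true homology.
    Deterministic given (params, rng state); stream order is root codons
    first, then branches in preorder with sites in left-to-right order.
    """
    rng = _as_rng(params.seed) if rng is None else rng
    freqs = params.root_freqs()
    site_class, omegas = _site_omega_classes(params)
    rates = [codon_rate_matrix(params.kappa, w, freqs) for w in omegas]
    length = params.codon_length

    root_states = rng.choice(_N_CODONS, size=length, p=freqs)
    states: dict[int, np.ndarray] = {id(gene_tree.root): root_states}
    pmat_cache: dict[tuple[int, float], np.ndarray] = {}

    for node in gene_tree.preorder():
        if node is gene_tree.root:
            continue
        parent_states = states[id(node.parent)]
        child_states = parent_states.copy()
        for ci in range(len(omegas)):
            sites = np.nonzero(site_class == ci)[0]
            if sites.size == 0:
                continue
            key = (ci, round(node.length, 12))
            if key not in pmat_cache:
                pmat_cache[key] = expm(rates[ci] * node.length)
            p = pmat_cache[key]
            cum = np.cumsum(p, axis=1)
            u = rng.random(sites.size)
            rows = cum[parent_states[sites]]
            child_states[sites] = (rows < u[:, None]).sum(axis=1)
        states[id(node)] = child_states

    rows = {}
    for leaf in gene_tree.leaves():
        codons = states[id(leaf)]
        rows[leaf.name] = "".join(SENSE_CODONS[s] for s in codons)
    msa = AlignedSet(rows, alphabet_kind="codon")

    labels = {}
    for name in msa.ids:
        if name.endswith("_A") or name.endswith("_B"):
            labels[name] = (name[:-2], name[-1])
        else:
            labels[name] = (name, "A")
    truth = SimTruth(
        params=params,
        species_tree=gene_tree,  # overwritten by simulate_family
        gene_tree=gene_tree,
        alignment=msa,
        labels=labels,
    )
    return msa, truth


def simulate_family(params: SimParams) -> SimTruth:
    """One full run: species tree -> duplication -> codon alignment + truth."""
    rng = np.random.default_rng(params.seed)
    if params.tree_shape == "yule":
        species_tree = simulate_species_tree(params.n_species, rng, params.total_height)
    else:
        species_tree = PhyloTree.from_newick(params.tree_shape)
    gene_tree = graft_duplication(species_tree, params.rate_multiplier_r)
    _, truth = simulate_codon_msa(gene_tree, params, rng=rng)
    truth.species_tree = species_tree
    return truth


def protein_alignment(codon_msa: AlignedSet) -> AlignedSet:
    """Translate a gapless codon alignment row-by-row."""
    rows = {}
    for rid, row in codon_msa.rows.items():
        if "-" in row:
            raise ValueError("protein_alignment expects a gapless codon alignment")
        rows[rid] = "".join(
            CODON_TO_AA[row[i : i + 3]] for i in range(0, len(row), 3)
        )
    return AlignedSet(rows, alphabet_kind="protein")


# ---------------------------------------------------------------------------
# Protein-architecture decoys for the triage classifier
# ---------------------------------------------------------------------------

_HYDROPHOBIC = "LIVFA"
_POLAR = "DENQKRSTGH"
_MIXED = "ACDEFGHIKLMNPQRSTVWY"

# PS00141-conforming aspartyl active-site core and a broken variant whose
# Asp-Ser-Gly core survives but whose flanks violate the pattern.
_MOTIF_MATCH = "ILVDTGSSNFAV"
_MOTIF_MATCH2 = "AIVDSGTSNLGV"
_MOTIF_BROKEN = "KSIVDSGTTNLR"


def _template_rng() -> np.random.Generator:
    # fixed internal seed: templates are constants of the generator
    return np.random.default_rng(853211)


def _rand_stretch(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(pool[i] for i in rng.integers(len(pool), size=n))


def _build_templates() -> tuple[str, str, set[int], set[int]]:
    """Returns (bace_template, cathepsin_template, bace_mask, cath_mask).

    Masks are 0-based positions that seeded noise must never touch (signal
    peptide, motifs, transmembrane stretch, and the cathepsin polar tail).
    """
    rng = _template_rng()
    # --- BACE-like: 505 residues
    sp = "M" + _rand_stretch(rng, _HYDROPHOBIC, 16) + "RSA"  # 1..20
    body1 = _rand_stretch(rng, _MIXED, 69)  # 21..89
    motif1 = _MOTIF_MATCH  # 90..101
    body2 = _rand_stretch(rng, _MIXED, 182)  # 102..283
    distal = _MOTIF_BROKEN  # 284..295
    body3 = _rand_stretch(rng, _MIXED, 174)  # 296..469
    ctm = _rand_stretch(rng, _HYDROPHOBIC, 25)  # 470..494
    tail = _rand_stretch(rng, _POLAR, 11)  # 495..505
    bace = sp + body1 + motif1 + body2 + distal + body3 + ctm + tail
    assert len(bace) == 505
    bace_mask = set(range(0, 20)) | set(range(89, 101)) | set(range(283, 295))
    bace_mask |= set(range(469, 505))

    # --- cathepsin-like: 390 residues, a diverged soluble copy of the core
    sp_c = "M" + _rand_stretch(rng, _HYDROPHOBIC, 15) + "TSEA"  # 1..20
    core = list(bace[20:330])  # positions 21..330 of the BACE template
    mutate = rng.random(len(core)) < 0.45
    for i in np.nonzero(mutate)[0]:
        core[i] = _MIXED[int(rng.integers(len(_MIXED)))]
    core = "".join(core)
    # proximal motif at the same relative offset; distal site made PS00141+
    core = core[:69] + _MOTIF_MATCH + core[81:]
    core = core[:243] + _MOTIF_MATCH2 + core[255:]
    polar_tail = _rand_stretch(rng, _POLAR, 60)  # keeps the C-terminus soluble
    cath = sp_c + core + polar_tail
    assert len(cath) == 390
    cath_mask = set(range(0, 20)) | set(range(89, 101)) | set(range(263, 275))
    cath_mask |= set(range(len(cath) - 100, len(cath)))
    return bace, cath, bace_mask, cath_mask


_TEMPLATES = _build_templates()


def decorate_architecture(
    kind: Literal["bace-like", "cathepsin-like"],
    seed: int | np.random.Generator,
) -> Sequence:
    """A seeded protein decoy with the requested architecture.

    bace-like: ~505 residues, hydrophobic N-terminal signal window, a single
    proximal PS00141 active-site match (the distal Asp site is present but
    pattern-broken, as in BACE1), and a >=19-residue hydrophobic stretch near
    the C-terminus. cathepsin-like: ~390 residues, signal peptide and two
    PS00141 matches but a polar C-terminus (no transmembrane stretch).
    Non-feature positions carry 8% seeded substitution noise.
    """
    bace, cath, bace_mask, cath_mask = _TEMPLATES
    if kind == "bace-like":
        template, mask = bace, bace_mask
    elif kind == "cathepsin-like":
        template, mask = cath, cath_mask
    else:
        raise ValueError(f"unknown architecture kind {kind!r}")
    rng = _as_rng(seed)
    seq = list(template)
    hits = rng.random(len(seq)) < 0.08
    for i in np.nonzero(hits)[0]:
        if int(i) in mask:
            continue
        pool = _POLAR if (kind == "cathepsin-like" and i >= len(seq) - 100) else _MIXED
        seq[i] = pool[int(rng.integers(len(pool)))]
    # small seeded length jitter at the very C-terminus
    extra = int(rng.integers(0, 9))
    seq.extend(_POLAR[i] for i in rng.integers(len(_POLAR), size=extra))
    tag = "bace" if kind == "bace-like" else "cath"
    sid = seed if not isinstance(seed, np.random.Generator) else rng.integers(10**6)
    return Sequence(id=f"{tag}_decoy_{sid}", residues="".join(seq))
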