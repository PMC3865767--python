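# Methods

This note describes the models, estimators and numerical choices behind
`paradiv`, in the order a run uses them: the synthetic gene-family generator,
homolog triage, distance trees, rate asymmetry, Ka/Ks counting, and block
extraction. Defaults are stated with units and the reason they were chosen.

## Synthetic gene families (`paradiv.simulate`)

**What it emulates.** A single-copy protease gene radiates with a species
tree; a duplication preceding the radiation yields paralog clades A and B;
clade B evolves faster by a constant factor; selective constraint varies
along the gene (relaxed termini, frozen catalytic core). This is the
situation the downstream estimators are designed for, and the simulator is
the package's truth channel: every statistic can be checked against the
parameters that generated the data.

**Species tree.** Yule process: with k lineages the next speciation waits
Exp(k) and splits a uniformly chosen lineage; the root splits at time zero.
Branch lengths are rescaled so every root-to-tip path equals `total_height`
(default **0.1 expected nucleotide substitutions per site**, a moderate
divergence that keeps synonymous sites well below saturation across a
reasonable species sample). The tree is ultrametric by construction.

**Duplication.** `graft_duplication` places two copies of the species tree
under a new root. Each copy hangs from a stem of `stem_frac` (default 0.5)
times the species-tree height — the post-duplication interval before the
radiation — and every branch of copy B, stem included, is multiplied by the
rate multiplier r (default **2.0**, a clade-B acceleration of the size seen
in fast/slow paralog pairs). Within-clade distances never traverse the stems,
so clade-internal statistics are independent of `stem_frac`; the stems exist
so the A|B split is a real, supportable internal edge.

**Codon process.** States are the 61 sense codons. A single-nucleotide change
is accepted at relative rate 1 if synonymous and ω if nonsynonymous, with
transitions weighted κ (defaults **ω = 0.1**, strong purifying selection, and
**κ = 2.0**, a typical transition/transversion ratio); multi-nucleotide
instantaneous changes have rate zero, and rates into stop codons are zero, so
no lineage ever passes through a stop (exclusion in distribution, exactly the
behaviour of a rejection sampler but without the approximation). ω may vary
along the gene via a partition table that must tile the sequence. The
generator matrix is scaled so the mean leaving rate at the root codon
distribution equals 3 substitutions per codon: **one branch-length unit = one
expected nucleotide substitution per nucleotide site at the root
composition**, which makes simulated branch lengths directly comparable to
the protein distance estimators. Root codons are drawn from the root
distribution (uniform over the 61 sense codons by default); each branch is
simulated by sampling child states from exp(Qt) column-by-column. No indels
are generated, so alignment columns are the true homology — intentional,
because the estimators consume alignments and alignment construction is out
of scope.

**Determinism.** One `numpy` Generator seeded by the single integer seed
drives a run; stream order is species tree, then root codons, then branches
in preorder. Identical parameters reproduce byte-identical FASTA/Newick
artifacts.

**Architecture decoys.** `decorate_architecture` emits protein decoys for the
triage classifier from two fixed templates: a BACE-like one (~505 aa: Met +
16 hydrophobic residues as a signal window; one PS00141-conforming aspartyl
active-site motif at residue 90; a second catalytic-Asp site at 284 whose
flanks deliberately violate the pattern, as in BACE1; a 25-residue
hydrophobic stretch at 470–494; polar tail) and a cathepsin-like one
(~390 aa: a 45%-diverged copy of the protease core with *both* motif sites
PS00141-conforming, no hydrophobic C-terminal stretch, polar final 60
residues). Decoys carry 8% seeded substitution noise outside the feature
regions plus 0–8 residues of tail-length jitter. The masks guarantee the
designed predictor outcomes (signal peptide and motif counts in both classes;
CTM presence only in the BACE-like class) for every seed.

**What the simulator does not model** — hence what passing tests do and do
not show about real data: no indels or alignment error, no among-site rate
variation within an ω partition, no codon-usage bias, no heterotachy, and
architecture decoys whose divergence from their template is i.i.d. noise
rather than phylogenetically structured. Recovery results here demonstrate
estimator correctness under the model, not robustness to real-data artifacts.

## Homolog triage (`paradiv.align`, `paradiv.triage`)

**Alignment.** Smith–Waterman local alignment with affine gaps via
Biopython's `PairwiseAligner`, BLOSUM62, gap open 11 / extend 1 (a gap of
length k costs 11 + k), the scoring the similarity thresholds were calibrated
against. Among co-optimal alignments the aligner's first is reported —
deterministic, which is the property downstream code relies on. Identity is
identical columns over the full alignment length *including* gap columns;
coverage is the aligned span of the shorter sequence over its length.
E-values are deliberately not computed (they depend on database size);
identity/coverage/gap thresholds carry the evidence instead.

**Features.** Kyte–Doolittle hydropathy with truncated windows at the ends.
Signal peptide: some 8-residue window fully inside residues 1–40 with mean
hydropathy ≥ 1.5. CTM: some 19-residue window (a minimal membrane-spanning
length) starting within the final 80 residues with mean ≥ 1.6. Both are fixed
heuristics standing in for dedicated predictors; thresholds are config.
Active-site motifs: PROSITE PS00141 translated to a regular expression,
non-overlapping leftmost matches, each reporting the catalytic Asp of its
D-[ST]-G core. "Proximal" means starting within the first 40% of the ORF.

**Classification.** Seven computable criteria: (1) reciprocal best hit into
the family reference, (2) identity ≥ 35% with coverage ≥ 0.7 of the shorter
ORF and gaps ≤ 15%, (3) identity to every cathepsin reference strictly below
identity to the family reference, (4) length at least 60 residues above the
cathepsin median, (5) signal peptide, (6) CTM, (7) motif count equal to the
family expectation (one proximal match). Criteria 1, 2 and 6 are mandatory:
all seven true → family member ("bace-like"); mandatory true but
corroboration missing → borderline; otherwise cathepsin-like. An exon count
(≥ 9) can be supplied as metadata and acts as corroboration only — it is
never computed from sequence. The structure makes the classifier monotone:
relaxing a threshold can only promote a label.

**Substrate presence/absence.** A substrate is present in a proteome iff its
reciprocal-best-hit-confirmed local alignment reaches 25% identity over at
least half the substrate; per-cell supporting numbers are emitted.

## Distance trees (`paradiv.phylo`)

p-distances use pairwise deletion (columns with `-` or `X` in either row are
skipped) because real family sets contain partial sequences; the default
model is the Poisson correction d = −ln(1 − p), with `observed` as fallback.
BIONJ (Gascuel 1997) follows the standard neighbor-joining Q-criterion and
branch-length estimates but propagates pair variances through the
variance-weighted reduction (λ clamped to [0,1]; λ = ½ when the joined pair's
variance is zero). Ties in Q break on the smallest (row, col) index pair in
the current cluster ordering; negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch, preserving local path
lengths; the final three clusters are resolved by the exact closed form on a
trifurcating root. On additive matrices the algorithm recovers the generating
tree exactly (topology and branch lengths to 1e-9), the property the test
suite enforces. Bootstrap supports resample alignment columns (whole codons
for codon alignments), rebuild the tree per replicate, and report the
percentage of replicates containing each bipartition of the point tree.

## Rate asymmetry (`paradiv.asymmetry`)

Inputs are any distance matrix plus a clade table (id, clade A/B, species;
at most one id per species per clade, with an explicit exclusion list for
extra paralogs). For every species pair present in both clades the module
records d_A, d_B, their ratio and direction. The summary reports the
arithmetic mean of per-pair ratios **and** the ratio of clade means — these
are different aggregates (a mean of ratios exceeds the ratio of means under
noise) and publishing both avoids ambiguity. Ties are exact (epsilon 1e-12)
by default. The sign test is a two-sided exact binomial on non-tied pairs,
labelled an interpretive extension: the per-pair directions share tree
branches, so they are positively correlated and the binomial p-value is
anticonservative as a strict test. At r = 1 the direction counts are centred
on n/2 but overdispersed relative to a binomial by roughly the ratio of
shared-branch to pair-specific variance (~9× under the default study
conditions); the test suite checks the centred mean across seeds rather than
per-seed binomial coverage for that null.

## Ka/Ks (`paradiv.kaks`)

**Sites.** For each sense codon, each of its nine single-nucleotide neighbors
contributes one third of a site to the synonymous or nonsynonymous class;
neighbors that are stops are dropped *without renormalisation* (so
s + n ≤ 3, with equality iff no stop neighbor). Alternatives exist in the
literature and change site counts slightly; the convention is fixed and
documented here.

**Differences.** Codons differing at one position classify directly; 2–3
position pairs average over all orderings of single steps, excluding paths
through stops; a codon pair with no stop-free path is skipped and flagged.

**NG86 pairwise.** S and N are the mean of the two rows' summed site counts;
pS = Sd/S, pN = Nd/N; Jukes–Cantor correction k = −¾ ln(1 − 4p/3), flagged
saturated at p ≥ 0.75. The dataset aggregate is the mean of per-pair Ka and
per-pair Ks over all unordered pairs, ratio = mean Ka / mean Ks, with the
per-pair table emitted alongside.

**SLAC-style.** Ancestral codons come from Fitch parsimony run per nucleotide
column (leaf gaps are missing data); among minimum-change assignments each
internal codon prefers non-stop states, then the fewest nonsynonymous changes
against its parent, then lexicographic order — a deterministic tie-break that
cannot change the parsimony score. Multifurcations are resolved with
zero-length edges (parsimony-neutral) before the pass. Per-branch differences
(path-averaged as above) are summed over the tree; site counts average over
all node sequences, ancestors included; the ratio is
(ΣNd/N) / (ΣSd/S). The reported Ka/Ks are tree totals, not per-unit-length
rates — only the ratio is scale-free. This substitutes counting on a
BIONJ/Fitch scaffold for a likelihood engine's ML branch lengths and
ancestors; agreement with likelihood-based SLAC is expected at the level of
the ratio's second decimal, not bit-exact.

**Partitions.** Residue spans (1-based inclusive) on a named reference row
map through that row's gaps to alignment columns, expanded ×3 to nucleotides;
a whole-alignment "All" row is always emitted. When partitions tile the
reference, their (Sd, Nd) sum to the whole-alignment counts exactly.

**Ratios with Ks = 0** are reported as undefined via a flag, never as
infinity or zero — a 0.000 ratio in output always means Ka = 0.

**Estimator bias.** Both counting methods ignore the transition bias when
counting sites, which deflates ω̂ when κ > 1 (measured ≈ 20% at κ = 2,
ω = 0.1 under the default simulator settings); median recovery stays within
±30% of the generative value at ω ∈ {0.05, 0.15} (8 taxa, 400 codons), which
is what the acceptance checks assert.

## Conserved blocks (`paradiv.blocks`)

Column information content is IC = log2 20 − H over observed (non-gap)
residues, optionally with the small-sample correction 19/(2 ln2 · n), floored
at zero. Block extraction is deterministic: rows with more than 50% gaps are
dropped (the very-divergent/fragmentary exclusions of block-based displays);
a column is eligible iff gap-free among retained rows and IC ≥ the threshold
(default **2.0 bits**, with `min_width` 6); maximal eligible runs of at least
`min_width` columns become blocks, reported N→C with inter-block spacing.
Logo letter heights are f_a · IC per column and sum to the column IC. This is
a column-scoring replacement for Gibbs-sampling block finders — reproducible
and threshold-explicit, at the cost of not modelling block mobility.

## Pipeline (`paradiv.pipeline`, `paradiv.cli`)

A JSON config with one global seed drives simulate → triage → tree →
asymmetry → Ka/Ks → blocks; per-stage seeds derive from the global seed by
fixed offsets (simulate +0, decoy triage +1, bootstrap +2) so stages can be
rerun in isolation. Unknown config keys are rejected by name. Every artifact
is plain text; a consolidated `report.json` aggregates the per-stage
summaries, and a failed stage aborts its dependents while independent stages
still run.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run entirely on generated data:
50 additive matrices of 5–10 leaves for BIONJ exactness; 200 random pairs of
≤ 12 residues against the alignment oracle; 200 (60 in the script) random
≤ 6-leaf, ≤ 5-codon instances against exhaustive parsimony; 20 seeds (10 in
the script) of the 10-species, 500-codon, r = 2 family for asymmetry
recovery; 20 (10) seeds of 8-taxon, 400-codon alignments per ω for estimator
recovery; 20 + 20 architecture decoys for triage separation. These sizes give
stable medians and rates while keeping a full run in the tens of seconds.
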