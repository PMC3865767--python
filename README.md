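# paradiv

Analysis toolkit for **post-duplication paralog divergence** in protein
families, built around the BACE1/BACE2 aspartyl-protease case: after a gene
duplication, did one paralog clade evolve faster than the other, where along
the gene does purifying selection bite, and how do you tell a true family
member from its nearest relatives (cathepsin-like proteases)?

It is a library first (with a thin `paradiv` command-line layer) aimed at
molecular-evolution practitioners who have a protein alignment, coding
sequences and clade assignments, and want reproducible, inspectable versions
of the classic analyses:

* **Homolog triage** — explicit, computable versions of the evidence used to
  call a candidate ORF BACE-like: reciprocal best hit, identity/coverage/gap
  thresholds (Smith–Waterman, BLOSUM62, gap open 11 / extend 1), a length
  excess over cathepsins, Kyte–Doolittle hydropathy heuristics for the signal
  peptide and the C-terminal transmembrane stretch (CTM), and PROSITE PS00141
  active-site motif counting. Plus a substrate presence/absence matrix across
  proteomes.
* **BIONJ distance trees** — Poisson-corrected p-distances under pairwise
  deletion, the variance-weighted neighbor-joining agglomeration (exact on
  additive matrices), and column-bootstrap supports.
* **Paralog rate asymmetry** — for species present in both paralog clades,
  per-species-pair distances d_A and d_B, the arithmetic mean of per-pair
  ratios d_B/d_A (and, separately, the ratio of the two clade means),
  direction counts, and a two-sided exact binomial sign test.
* **Counting-based Ka/Ks** — Nei–Gojobori (1986) pairwise counting with
  Jukes–Cantor correction, and a SLAC-style variant (Fitch-parsimony
  ancestors on a tree, per-branch counts), both over whole genes and over
  domain/exon partitions mapped through a reference row.
* **Conserved blocks** — deterministic extraction of ungapped high-information
  runs from an alignment, with per-column information content and
  sequence-logo letter heights.
* **A codon-level gene-family simulator** — Yule species tree, duplication
  with a clade-specific rate multiplier, per-partition omega (dN/dS), kappa
  transition bias, stop-codon exclusion, plus protein-architecture decoys —
  so every stage is testable against known truth without any downloads.

## The statistics in brief

For rows i, j of a protein alignment, p = mismatches / compared columns
(columns with a gap or `X` in either row are skipped) and the Poisson-corrected
distance is d = −ln(1 − p). With species s₁ … s_n present in both paralog
clades, each unordered pair (s_i, s_j) yields d_A and d_B; the headline
asymmetry statistic is mean(d_B/d_A) with a sign test on the direction counts.

For Ka/Ks, every sense codon contributes synonymous/nonsynonymous site counts
from its nine single-nucleotide neighbors (stop neighbors dropped, so
s + n ≤ 3); observed differences in multi-hit codons are averaged over all
stop-free orderings of single steps; pS = Sd/S and pN = Nd/N are corrected by
k = −¾ ln(1 − 4p/3); ω = Ka/Ks < 1 indicates purifying selection. The
SLAC-style variant reconstructs ancestral codons by Fitch parsimony on a
(BIONJ or supplied) tree and sums per-branch counts over the whole tree.

## Worked example

```python
from paradiv.asymmetry import clade_table_from_labels, pair_table, summarize
from paradiv.phylo import distance_matrix
from paradiv.simulate import SimParams, protein_alignment, simulate_family

truth = simulate_family(
    SimParams(n_species=10, rate_multiplier_r=2.0, codon_length=500, seed=0)
)
dm = distance_matrix(protein_alignment(truth.alignment), model="poisson")
summary = summarize(pair_table(dm, clade_table_from_labels(truth.labels)))
print(summary.mean_d_a, summary.mean_d_b)
print(summary.mean_ratio, summary.n_b_greater, summary.sign_test_p)
```

prints

```
0.0986196795936647 0.20500267773480374
2.167657609343311 45 5.684341886080802e-14
```

meaning: across the 45 species pairs, clade-A orthologs differ by 0.099
substitutions/site on average and clade-B orthologs by 0.205; the mean
per-pair B/A ratio of 2.17 recovers the generative 2× acceleration, all 45
pairs point the same way, and the sign test rejects rate symmetry outright.

The same run from the shell:

```bash
paradiv simulate --n-species 10 --rate-multiplier 2 --length 500 --seed 0 --out-dir fam
paradiv tree --msa fam/protein_alignment.fasta --matrix-out fam/dist.tsv --out fam/tree.nwk
paradiv asymmetry --matrix fam/dist.tsv --clades fam/labels.tsv --out fam/pairs.tsv
```

`examples/` holds one short script per capability (simulation, triage, trees,
asymmetry, partitioned Ka/Ks, blocks, full pipeline), each printing the
numbers it computes and what they mean.

## Limitations

The simulator is a stand-in generative model (no published generative model
exists for this gene family): no indels, no among-site rate variation beyond
the omega partitions, uniform codon frequencies by default. The signal-peptide
and CTM calls are hydropathy-window heuristics, not SignalP/TMHMM
reimplementations; E-values are deliberately not computed. See
`docs/methods.md` for the full model description, parameter defaults, and
known limitations.
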