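"""Simulate a duplicated gene family with a 2x-accelerated paralog clade.

The generator builds a Yule species tree, duplicates it at the root (each copy
hanging from a post-duplication stem), multiplies every clade-B branch by the
rate multiplier, and evolves codons under a kappa/omega substitution process.
The output alignment has no indels, so its columns are the true homology.
"""

from paradiv.simulate import SimParams, protein_alignment, simulate_family

params = SimParams(n_species=6, codon_length=300, rate_multiplier_r=2.0,
                   kappa=2.0, seed=42)
truth = simulate_family(params)

print(f"gene tree: {truth.gene_tree.to_newick()[:90]}...")
print(f"{len(truth.alignment.ids)} sequences x {params.codon_length} codons")
prot = protein_alignment(truth.alignment)
first = truth.alignment.ids[0]
print(f"{first} protein starts: {prot.rows[first][:40]}...")
clades = {}
for sid, (species, clade) in truth.labels.items():
    clades.setdefault(clade, []).append(sid)
print(f"clade A: {sorted(clades['A'])}")
print(f"clade B: {sorted(clades['B'])}")
# Clade B carries twice the expected substitutions per branch; every later
# stage (tree, asymmetry, Ka/Ks) can be checked against this known truth.
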