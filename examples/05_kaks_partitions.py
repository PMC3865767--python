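"""Partitioned Ka/Ks by NG86 pairwise counting and SLAC-style tree counting.

The simulated gene has a relaxed 5' region (omega 0.3, first 60 codons) and a
strongly constrained remainder (omega 0.05) — the pattern seen when terminal
exons evolve under weaker purifying selection than a catalytic core. Both
estimators should rank the partitions correctly.
"""

import numpy as np

from paradiv.kaks import partition_kaks
from paradiv.phylo import build_bionj, distance_matrix
from paradiv.seqio import Partition, PartitionTable
from paradiv.simulate import (
    SimParams,
    protein_alignment,
    simulate_codon_msa,
    simulate_species_tree,
)

rng = np.random.default_rng(11)
tree = simulate_species_tree(8, rng, total_height=0.1)
params = SimParams(
    n_species=8, codon_length=400,
    omega_by_partition=[("five_prime", 1, 60, 0.3), ("core", 61, 400, 0.05)],
    seed=11,
)
msa, _ = simulate_codon_msa(tree, params, rng=rng)

table = PartitionTable([Partition("five_prime", 1, 60), Partition("core", 61, 400)])
bionj = build_bionj(distance_matrix(protein_alignment(msa), "poisson"))
df = partition_kaks(msa, table, reference_id=msa.ids[0], method="both", tree=bionj)
print(df[["partition", "method", "S_sites", "N_sites", "Sd", "Nd", "Ks", "Ka",
          "KaKs"]].to_string(index=False))
# Ka/Ks well below 1 everywhere indicates purifying selection; the relaxed
# 5' partition shows the higher ratio under both methods.
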