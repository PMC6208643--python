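"""Simulate a host phylogeny and tune the phylogenetic signal of its trait.

Builds a 25-species pure-birth host tree (height 1), evolves a continuous
host trait (think gut pH) under Brownian motion on delta-transformed trees,
and shows how the realized Blomberg K responds to delta: delta << 1 pushes
divergence toward the root (clade-structured trait, K >> 1), delta >> 1
pushes it toward the tips (no signal, K -> 0).
"""

import numpy as np

from phylosym import TraitEvolParams, simulate_host_trait, simulate_yule_tree

tree = simulate_yule_tree(25, seed=42, prefix="H")
print(f"host tree: {tree.count(tips=True)} tips, height "
      f"{max(tree.distance(t) for t in tree.tips()):.3f}")

for delta in (0.01, 0.1, 1.0, 10.0, 1000.0):
    ks = [
        simulate_host_trait(
            tree, TraitEvolParams(delta=delta, seed=s)
        )[1].mean_k
        for s in range(50)
    ]
    print(f"delta={delta:7g}  median Blomberg K = {np.median(ks):6.3f}")

print(
    "\nBlomberg K ~ 1 is the plain-Brownian expectation; values above ~1.5 "
    "mean the trait\nstrongly tracks deep clades, values near 0 mean it is "
    "phylogenetically random."
)
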