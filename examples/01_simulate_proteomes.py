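"""Simulate a labeled species tree and a protein family with ground truth.

Builds an 8-species tree spanning three supergroups, evolves one family with
duplications and losses along it, and assembles per-species proteomes with
decoys. The printed counts come straight from the simulator's event log, so
they are exact ground truth for benchmarking the downstream stages.
"""

from orthoprof import FamilySpec, emit_proteomes, evolve_family, simulate_species_tree

tree = simulate_species_tree(
    8, {"Opisthokonta:Fungi": 3, "Amoebozoa": 2, "SAR": 3}, seed=5
)
print("species tree:", tree.newick())

spec = FamilySpec(
    "demo_family", duplication_rate=0.6, loss_rate=0.25, substitution_scale=0.4
)
sequences, truth = evolve_family(tree, spec, seed=3)
print(f"\nfamily evolved into {len(sequences)} genes:")
for species, genes in sorted(truth.genes_by_species.items()):
    print(f"  {species}: {len(genes)} copies")
print("events:", [(e.kind, e.branch, e.classification) for e in truth.events])
# each 'duplication' adds a lineage on that branch; each 'loss' removes one —
# replaying the log reproduces the per-species copy numbers exactly

proteomes, truth_df = emit_proteomes(
    [(sequences, truth)], tree.species_table(), n_decoys_per_species=6, seed=5
)
print(f"\nproteomes: {len(proteomes)} species, sizes:",
      {s: len(p) for s, p in sorted(proteomes.items())})
print("(family genes + 6 unrelated order-2 Markov decoys per species)")
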