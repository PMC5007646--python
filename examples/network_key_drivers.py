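"""Recover a planted bridge driver on a synthetic interaction network.

Builds a 200-gene network with two 15-gene disease modules and one bridge
hub wired to both, expands each module's seeds by random walk with restart,
cuts each ranked expansion at the running-sum peak, intersects the
expansions, and scores every gene for key-driver enrichment.
"""

from driverscan import (
    common_genes, expand_seed_set, identify_key_drivers, simulate_network,
)

truth = simulate_network(n_genes=200, p_background=0.03,
                         module_spec=(15, 15, 0.8), driver_spec=(1, 30),
                         rng_seed=7)
net = truth.network
(planted,) = truth.drivers
print(f"network: {net.n} genes, {net.graph.number_of_edges()} edges; "
      f"planted driver {planted}")

res_a = expand_seed_set(net, truth.seeds_a, truth.seeds_b)
res_b = expand_seed_set(net, truth.seeds_b, truth.seeds_a)
print(f"expansion A: cutoff rank {res_a.cutoff_rank}, "
      f"{len(res_a.predicted)} predicted genes")
print(f"expansion B: cutoff rank {res_b.cutoff_rank}, "
      f"{len(res_b.predicted)} predicted genes")

common = common_genes(res_a, res_b, include_seeds=True)
print(f"common genes across the two expansions: {len(common)}")

records = identify_key_drivers(net, common, driver_alpha=1e-8)
top = records[0]
print(f"top-ranked gene: {top.gene} with {top.m_common}/{top.n_neighbors} "
      f"neighbors in the common set, FDR p = {top.p_fdr:.2e}")
print(f"planted driver recovered at rank 1: {top.gene == planted}")

# The bridge hub touches both modules, so nearly all its neighbors land in
# the common set; its hypergeometric enrichment dwarfs every background
# gene's and it is flagged as a key driver (FDR p far below 1e-8).
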