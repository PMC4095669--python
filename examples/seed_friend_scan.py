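"""Score every gene's connectivity to the seed set and call its friends.

A gene with total degree n, of which k neighbours are seed genes, gets the
upper-tail hypergeometric probability of drawing >= k seeds in n draws
from the universe; genes below p = 1e-8 are coexpression "friends" of the
seed set.  Seed genes themselves are tested against the other seeds
(self-connectivity), mirroring the question "is the grouped seed module
itself coexpressed?".
"""

from coexnet import (
    SeedSet,
    SimulationConfig,
    build_network,
    call_friends,
    generate_paired_dataset,
    seed_self_connectivity,
    test_all_genes,
)

normal, _, truth = generate_paired_dataset(SimulationConfig(rng_seed=1))
network = build_network(normal)
seed = SeedSet(truth.seed_genes, name="planted_seed")

results = test_all_genes(network, seed)
print("top genes by seed-connectivity (gene, k seed neighbours, degree n, log10 p):")
for r in results[:5]:
    print(f"  {r.gene}  k={r.k:3d}  n={r.n:3d}  log10p={r.log10_p:8.1f}")

friends = call_friends(results, seed=seed, alpha=1e-8)
connected = seed_self_connectivity(results, seed, alpha=1e-8)
recall = len(friends.members & truth.true_friends) / len(truth.true_friends)
print(f"seed self-connectivity: {len(connected)}/{len(truth.seed_genes)} seed genes")
print(f"friends called: {len(friends.members)}; recall of planted friends: {recall:.2f}")
print("(with strong loadings nearly all planted structure is recovered;"
      " the few extra friends are background genes that chance-correlate"
      " with the latent factor)")
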