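"""Attack and node-addition robustness of a scale-free network.

Removes nodes under four strategies from a Barabasi-Albert graph and
reports the fraction of removals needed to destroy 80% of the originally
reachable node pairs, then grows the network by random attachment and
tracks the largest connected component (LCC) and average path length (APL).
"""

from micronet import (
    make_fixture_graph, attack, random_attack_ci, add_nodes, apl,
)

net = make_fixture_graph("barabasi_albert", 200, param=2, seed=0)
print(f"fixture: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")

for strategy in ("cascading", "betweenness", "degree"):
    curve = attack(net, strategy, target=0.80)
    print(f"{strategy:>12}: fraction at 80% connectivity loss = "
          f"{curve.fraction_at_target:.3f}")
mean, (lo, hi) = random_attack_ci(net, target=0.80, n_boot=100, seed=0)
print(f"{'random':>12}: mean {mean:.3f} (95% CI {lo:.3f}-{hi:.3f})")
# Smaller fractions mean a more fragile network; targeted attacks with
# betweenness recomputation (cascading) dismantle it fastest, random
# removal slowest.

grown, trace = add_nodes(net, 100, attach_edges=1, rule="uniform", seed=1)
print(f"after adding 100 nodes: LCC {trace.lcc_size[0]} -> {trace.lcc_size[-1]}, "
      f"APL {apl(net):.3f} -> {trace.apl[-1]:.3f}")
# Uniform single-edge attachment grows the LCC by one per addition and
# stretches path lengths, since new nodes arrive at the periphery.
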