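"""Evolution of a TF-target regulatory state along a phylogeny.

A gene's regulatory state (target of the focal TF or not) flips along each
branch as a two-state CTMC with gain rate lam and loss rate mu.  This
script prints the transition matrix over one branch, the stationary target
fraction, and the probability of each observable leaf configuration on a
three-species tree.
"""

from tnevo import (
    Phylogeny,
    RateParams,
    enumerate_leaf_configs,
    leaf_config_probability,
    stationary_distribution,
    transition_matrix,
)

tree = Phylogeny.from_newick("((human:0.9,mouse:0.9):0.1,cow:1.0);")
rates = RateParams(lam=0.3, mu=0.7, pi_root=0.3)

print("Transition matrix over t = 0.9 (rows: from state 0/1, cols: to 0/1):")
print(transition_matrix(rates, 0.9).round(4))
# entry [0,1] is the chance a non-target becomes a target over that branch

pi0, pi1 = stationary_distribution(rates)
print(f"\nStationary target fraction lam/(lam+mu) = {pi1:.3f}")

print("\nP(leaf configuration) for every assignment of target (1) / non-target (0):")
total = 0.0
for cfg in enumerate_leaf_configs(tree.leaves):
    p = leaf_config_probability(tree, rates, cfg)
    total += p
    states = " ".join(f"{sp}={z}" for sp, z in sorted(cfg.items()))
    print(f"  {states}: {p:.4f}")
print(f"  (sum = {total:.6f}; the eight configurations form a distribution)")
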