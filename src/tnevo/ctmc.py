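"""Two-state CTMC of regulatory states on a phylogeny.

A gene's regulatory state Z in a species is binary: 1 if the gene is a
transcriptional target of the focal TF, 0 otherwise.  Z evolves along the
tree as a continuous-time Markov chain with gain rate ``lam`` (0->1) and
loss rate ``mu`` (1->0) per unit divergence time.  The probability of an
observed leaf configuration marginalizes the unobserved ancestral states by
summation over internal-node assignments (Felsenstein pruning); on a star
tree this reduces to the root-prior-weighted product of per-branch
transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .phylo import Phylogeny

__all__ = [
    "RateParams",
    "transition_matrix",
    "stationary_distribution",
    "config_root_likelihoods",
    "leaf_config_probability",
    "leaf_config_probability_bruteforce",
    "enumerate_leaf_configs",
    "config_array",
]


@dataclass(frozen=True)
class RateParams:
    """CTMC rates and root prior.

    ``lam``: rate of 0->1 (gain of regulation) per unit time; ``mu``: rate of
    1->0 (loss); ``pi_root``: probability that the root state is 1.
    """

    lam: float
    mu: float
    pi_root: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not (self.mu > 0 and np.isfinite(self.mu)):
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not (0.0 <= self.pi_root <= 1.0):
            raise ValueError(f"pi_root must be in [0, 1], got {self.pi_root}")

    @classmethod
    def with_stationary_root(cls, lam: float, mu: float) -> "RateParams":
        """Tie the root prior to the chain's stationary distribution."""
        return cls(lam=lam, mu=mu, pi_root=lam / (lam + mu))

    @property
    def root_prior(self) -> np.ndarray:
        return np.array([1.0 - self.pi_root, self.pi_root])


def transition_matrix(rates: RateParams, t: float) -> np.ndarray:
    """Transition probabilities of the regulatory state over time ``t``.

    Closed form for the 2-state chain with generator [[-lam, lam], [mu, -mu]]:
    P(0->1, t) = lam/(lam+mu) * (1 - exp(-(lam+mu) t)) and symmetrically for
    P(1->0, t).  Entry ``[x, y]`` is P(state y at time t | state x at 0).
    """
    if not (t >= 0):
        raise ValueError(f"t must be nonnegative, got {t}")
    s = rates.lam + rates.mu
    decay = np.exp(-s * t)
    p01 = rates.lam / s * (1.0 - decay)
    p10 = rates.mu / s * (1.0 - decay)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def stationary_distribution(rates: RateParams) -> tuple[float, float]:
    """Left fixed point of the transition matrix: (mu, lam)/(lam+mu)."""
    s = rates.lam + rates.mu
    return (rates.mu / s, rates.lam / s)


def config_array(configs: Sequence[Mapping[str, int]], leaves: Sequence[str]) -> np.ndarray:
    """Stack leaf configs into an (n_configs, n_leaves) 0/1 array in ``leaves`` order."""
    out = np.empty((len(configs), len(leaves)), dtype=np.int8)
    for i, cfg in enumerate(configs):
        if set(cfg) != set(leaves):
            raise ValueError(f"config keys {sorted(cfg)} do not match leaves {sorted(leaves)}")
        for j, sp in enumerate(leaves):
            z = cfg[sp]
            if z not in (0, 1):
                raise ValueError(f"state for {sp} must be 0 or 1, got {z}")
            out[i, j] = z
    return out


def config_root_likelihoods(
    tree: Phylogeny, rates: RateParams, configs: np.ndarray
) -> np.ndarray:
    """P(leaf config | root state) for a batch of configs.

    ``configs`` is (n_configs, n_leaves) over ``tree.leaves`` order.  Returns
    an (n_configs, 2) array whose ``[i, r]`` entry is the conditional
    probability of config ``i`` given root state ``r``, ancestral states
    summed out by pruning.
    """
    configs = np.asarray(configs)
    if configs.ndim != 2 or configs.shape[1] != tree.n_leaves:
        raise ValueError("configs must be (n_configs, n_leaves)")
    leaf_col = {name: j for j, name in enumerate(tree.leaves)}
    # partial[node][i, r] = P(observed leaves below node | node state r)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node in tree.leaf_names:
            z = configs[:, leaf_col[tree.leaf_names[node]]]
            part = np.zeros((configs.shape[0], 2))
            part[np.arange(configs.shape[0]), z] = 1.0
        else:
            part = np.ones((configs.shape[0], 2))
            for child in tree.children(node):
                pmat = transition_matrix(rates, tree.branch_lengths[child])
                part = part * (partial.pop(child) @ pmat.T)
        partial[node] = part
    return partial[tree.root]


def leaf_config_probability(
    tree: Phylogeny, rates: RateParams, config: Mapping[str, int]
) -> float:
    """P(Z_leaves = config | tree, lam, mu, pi_root), ancestral states marginalized."""
    arr = config_array([config], tree.leaves)
    cond = config_root_likelihoods(tree, rates, arr)[0]
    return float(cond @ rates.root_prior)


def leaf_config_probability_bruteforce(
    tree: Phylogeny, rates: RateParams, config: Mapping[str, int]
) -> float:
    """Exhaustive-enumeration oracle for :func:`leaf_config_probability`.

    Sums the root prior times per-branch transition probabilities over every
    assignment of states to every node.  Refuses trees with more than 12
    nodes.
    """
    nodes = sorted(tree.nodes)
    if len(nodes) > 12:
        raise ValueError("brute force limited to trees with <= 12 nodes")
    if set(config) != set(tree.leaves):
        raise ValueError("config keys must match tree leaves")
    pmats = {
        node: transition_matrix(rates, tree.branch_lengths[node])
        for node in nodes
        if node != tree.root
    }
    name = tree.leaf_names
    total = 0.0
    for bits in range(2 ** len(nodes)):
        states = {node: (bits >> i) & 1 for i, node in enumerate(nodes)}
        if any(states[leaf] != config[name[leaf]] for leaf in name):
            continue
        p = rates.root_prior[states[tree.root]]
        for node in nodes:
            if node == tree.root:
                continue
            p *= pmats[node][states[tree.parent[node]], states[node]]
        total += p
    return total


def enumerate_leaf_configs(leaves: int | Sequence[str]) -> list:
    """All 2^n leaf configurations in a stable binary-counting order.

    With species names, the names are sorted lexicographically and the first
    species is the most significant bit, so the list is in lexicographic
    order of state vectors; dict configs are returned.  With an integer, 0/1
    tuples are returned in the same order.
    """
    if isinstance(leaves, int):
        n = leaves
        names: Sequence[str] | None = None
    else:
        names = sorted(leaves)
        if len(set(names)) != len(names):
            raise ValueError("leaf names must be unique")
        n = len(names)
    if not (1 <= n <= 20):
        raise ValueError(f"number of leaves must be in 1..20, got {n}")
    out = []
    for bits in range(2**n):
        vec = tuple((bits >> (n - 1 - j)) & 1 for j in range(n))
        out.append(vec if names is None else dict(zip(names, vec)))
    return out
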