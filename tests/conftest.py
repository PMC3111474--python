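import numpy as np
import pytest

from tnevo.ctmc import RateParams
from tnevo.motif import SequenceModelParams, build_pssm
from tnevo.phylo import Phylogeny
from tnevo.simulate import SimScenario, simulate_dataset
from tnevo.model import groups_from_windows


@pytest.fixture(scope="session")
def tree3():
    return Phylogeny.from_newick("((A:0.9,B:0.9):0.1,C:1.0);")


@pytest.fixture(scope="session")
def rates():
    return RateParams(lam=0.3, mu=0.7, pi_root=0.3)


@pytest.fixture(scope="session")
def sharp_pssm():
    """A well-determined 8-mer motif on a uniform background."""
    probs = np.full((8, 4), 0.1 / 3)
    consensus = "ACGTACGT"
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = 0.9
    return build_pssm(probs)


@pytest.fixture(scope="session")
def seq_params():
    return SequenceModelParams(q=0.005, threshold=0.6)


@pytest.fixture(scope="session")
def strong_dataset():
    """Strong sequence + strong expression signal, shared across tests."""
    return simulate_dataset(SimScenario(seq_signal="strong", expr_signal="strong", m=300, seed=11))


@pytest.fixture(scope="session")
def strong_groups(strong_dataset, seq_params):
    return groups_from_windows(
        strong_dataset.windows, strong_dataset.labels, strong_dataset.pssm, seq_params
    )


def random_tree(rng: np.random.Generator, n_leaves: int) -> Phylogeny:
    """A random rooted binary-ish tree with uniform branch lengths."""
    names = [chr(ord("A") + i) for i in range(n_leaves)]
    # build by successive joins
    next_id = 0
    nodes = []
    leaf_names = {}
    for name in names:
        leaf_names[next_id] = name
        nodes.append(next_id)
        next_id += 1
    parent: dict[int, int] = {}
    lengths: dict[int, float] = {}
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        p = next_id
        next_id += 1
        parent[a] = p
        parent[b] = p
        lengths[a] = float(rng.uniform(0.05, 2.0))
        lengths[b] = float(rng.uniform(0.05, 2.0))
        nodes = [n for n in nodes if n not in (a, b)] + [p]
    return Phylogeny(parent=parent, branch_lengths=lengths, leaf_names=leaf_names, root=nodes[0])
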