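"""Generative simulator and cross-validation harness.

Synthetic datasets emulate the model's own generative process: leaf
regulatory states drawn from the two-state CTMC on a fixed three-species
tree, promoter windows with motif instances planted (at rate ``q_true``)
when the state is 1, and expression-cluster labels drawn from the target
(theta1) or background (theta0) multinomial.  Six canonical scenarios cross
two sequence-signal levels (PSSM sharpness and planting rate) with three
expression-signal levels (total-variation distance between theta1 and
theta0).  All randomness flows through a single seeded generator hierarchy,
so regeneration with the same scenario and seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .ctmc import RateParams, transition_matrix
from .expression import ExpressionParams
from .model import (
    ModelParams,
    OrthologGroup,
    em_fit,
    groups_from_windows,
    infer_states,
    prediction_accuracy,
)
from .motif import BASES, PSSM, SequenceModelParams, build_pssm
from .phylo import Phylogeny

__all__ = [
    "SimScenario",
    "SimDataset",
    "DEFAULT_TREE_NEWICK",
    "scenario_pssm",
    "scenario_expression_params",
    "simulate_states",
    "simulate_sequences",
    "simulate_expression",
    "simulate_dataset",
    "simulate_profiles",
    "crossvalidate",
]

# Three mammal-like species; branch lengths in units of 100 My, in the same
# spirit as human/mouse/cattle divergence times.
DEFAULT_TREE_NEWICK = "((speciesA:0.9,speciesB:0.9):0.1,speciesC:1.0);"

_SEQ_LEVELS = ("weak", "strong")
_EXPR_LEVELS = ("weak", "medium", "strong")

# sequence signal: (q_true, consensus-base probability of the planted PSSM)
_SEQ_PARAMS = {"weak": (0.004, 0.65), "strong": (0.01, 0.9)}
# expression signal: total-variation distance between theta1 and theta0
_EXPR_TV = {"weak": 0.1, "medium": 0.3, "strong": 0.6}

_CONSENSUS = "ACGTACGT"  # 8-mer scaffold for the scenario motif


@dataclass(frozen=True)
class SimScenario:
    """One synthetic study condition.

    ``seq_signal`` in {weak, strong} controls motif information (PSSM
    sharpness and planting rate q_true); ``expr_signal`` in {weak, medium,
    strong} controls theta1 vs theta0 divergence.  ``m`` is the number of
    ortholog groups; ``window_length`` the promoter window size in bp.
    """

    seq_signal: Literal["weak", "strong"] = "strong"
    expr_signal: Literal["weak", "medium", "strong"] = "strong"
    m: int = 500
    window_length: int = 500
    k_clusters: int = 4
    seed: int = 0
    tree_newick: str = DEFAULT_TREE_NEWICK
    rates: RateParams = field(default_factory=lambda: RateParams(lam=0.3, mu=0.7, pi_root=0.3))
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.seq_signal not in _SEQ_LEVELS:
            raise ValueError(f"seq_signal must be one of {_SEQ_LEVELS}")
        if self.expr_signal not in _EXPR_LEVELS:
            raise ValueError(f"expr_signal must be one of {_EXPR_LEVELS}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.window_length < len(_CONSENSUS):
            raise ValueError("window_length must fit at least one motif")

    @property
    def q_true(self) -> float:
        return _SEQ_PARAMS[self.seq_signal][0]

    @property
    def tree(self) -> Phylogeny:
        return Phylogeny.from_newick(self.tree_newick)

    @classmethod
    def six_scenarios(cls, m: int = 500, seed: int = 0, **kwargs) -> list["SimScenario"]:
        """The canonical 2 x 3 grid of sequence x expression signal levels."""
        return [
            cls(seq_signal=s, expr_signal=e, m=m, seed=seed, **kwargs)
            for s in _SEQ_LEVELS
            for e in _EXPR_LEVELS
        ]


def scenario_pssm(scenario: SimScenario) -> PSSM:
    """The scenario's planted motif: an 8-mer with the consensus base at
    probability 0.65 (weak) or 0.9 (strong), remainder spread evenly."""
    _, peak = _SEQ_PARAMS[scenario.seq_signal]
    rest = (1.0 - peak) / 3.0
    probs = np.full((len(_CONSENSUS), 4), rest)
    for i, b in enumerate(_CONSENSUS):
        probs[i, BASES.index(b)] = peak
    return build_pssm(probs, background=scenario.background, name=f"sim-{scenario.seq_signal}")


def scenario_expression_params(scenario: SimScenario) -> ExpressionParams:
    """theta0 uniform over K clusters; theta1 shifts mass delta (the TV
    distance) onto cluster 1, identically in every species."""
    k = scenario.k_clusters
    delta = _EXPR_TV[scenario.expr_signal]
    theta0 = np.full(k, 1.0 / k)
    theta1 = theta0.copy()
    theta1[0] += delta
    theta1[1:] -= delta / (k - 1)
    if np.any(theta1 <= 0):
        raise ValueError("expression signal too strong for this K")
    species = scenario.tree.leaves
    return ExpressionParams(
        theta0={sp: theta0.copy() for sp in species},
        theta1={sp: theta1.copy() for sp in species},
    )


@dataclass(frozen=True)
class SimDataset:
    """Simulated windows, labels and hidden truth for one scenario."""

    scenario: SimScenario
    windows: dict[str, list[str]]            # species -> window per group
    labels: dict[str, list[int]]             # species -> cluster label per group
    truth: list[dict[str, int]]              # per-group leaf configuration
    internal_states: list[dict[int, int]]    # per-group state of every tree node
    pssm: PSSM
    expr_truth: ExpressionParams

    @property
    def species(self) -> list[str]:
        return sorted(self.windows)

    @property
    def m(self) -> int:
        return len(self.truth)


def simulate_states(
    tree: Phylogeny, rates: RateParams, m: int, seed: int | np.random.Generator
) -> tuple[list[dict[str, int]], list[dict[int, int]]]:
    """Sample M leaf configurations from the CTMC: the root from pi_root,
    then each branch through its transition matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmats = {
        node: transition_matrix(rates, tree.branch_lengths[node])
        for node in tree.nodes
        if node != tree.root
    }
    order = [n for n in reversed(tree.postorder())]  # parents before children
    configs: list[dict[str, int]] = []
    internals: list[dict[int, int]] = []
    for _ in range(m):
        states: dict[int, int] = {tree.root: int(rng.random() < rates.pi_root)}
        for node in order:
            if node == tree.root:
                continue
            p1 = pmats[node][states[tree.parent[node]], 1]
            states[node] = int(rng.random() < p1)
        configs.append({name: states[leaf] for leaf, name in tree.leaf_names.items()})
        internals.append(states)
    return configs, internals


def _draw_background(rng: np.random.Generator, n: int, background: np.ndarray) -> list[str]:
    return [BASES[i] for i in rng.choice(4, size=n, p=background)]


def _draw_motif(rng: np.random.Generator, pssm: PSSM) -> str:
    return "".join(
        BASES[rng.choice(4, p=pssm.probs[i])] for i in range(pssm.width)
    )


def simulate_sequences(
    configs: Sequence[Mapping[str, int]],
    pssm: PSSM,
    scenario: SimScenario,
    seed: int | np.random.Generator,
) -> dict[str, list[str]]:
    """Per-species promoter windows: i.i.d. background when Z=0; when Z=1
    each position starts a planted motif (drawn from the PSSM) with
    probability q_true, else emits a background base."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    length = scenario.window_length
    if length < pssm.width:
        raise ValueError("window too short to plant a motif")
    background = np.asarray(scenario.background)
    species = sorted(configs[0])
    out: dict[str, list[str]] = {sp: [] for sp in species}
    for cfg in configs:
        for sp in species:
            if cfg[sp] == 0:
                seq = "".join(_draw_background(rng, length, background))
            else:
                parts: list[str] = []
                pos = 0
                while pos < length:
                    if pos + pssm.width <= length and rng.random() < scenario.q_true:
                        parts.append(_draw_motif(rng, pssm))
                        pos += pssm.width
                    else:
                        parts.append(BASES[rng.choice(4, p=background)])
                        pos += 1
                seq = "".join(parts)
            out[sp].append(seq)
    return out


def simulate_expression(
    configs: Sequence[Mapping[str, int]],
    expr: ExpressionParams,
    seed: int | np.random.Generator,
) -> dict[str, list[int]]:
    """Cluster labels: label ~ theta1 if Z=1 else theta0, independent per species."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = sorted(configs[0])
    out: dict[str, list[int]] = {sp: [] for sp in species}
    for cfg in configs:
        for sp in species:
            theta = expr.theta1[sp] if cfg[sp] == 1 else expr.theta0[sp]
            out[sp].append(int(rng.choice(theta.size, p=theta)) + 1)
    return out


def simulate_dataset(scenario: SimScenario) -> SimDataset:
    """Compose the three samplers under a seeded generator hierarchy."""
    root = np.random.SeedSequence(scenario.seed)
    s_states, s_seq, s_expr = root.spawn(3)
    tree = scenario.tree
    pssm = scenario_pssm(scenario)
    expr = scenario_expression_params(scenario)
    configs, internals = simulate_states(
        tree, scenario.rates, scenario.m, np.random.default_rng(s_states)
    )
    windows = simulate_sequences(configs, pssm, scenario, np.random.default_rng(s_seq))
    labels = simulate_expression(configs, expr, np.random.default_rng(s_expr))
    return SimDataset(
        scenario=scenario,
        windows=windows,
        labels=labels,
        truth=configs,
        internal_states=internals,
        pssm=pssm,
        expr_truth=expr,
    )


def simulate_profiles(
    labels: Sequence[int],
    n_conditions: int = 8,
    separation: float = 4.0,
    noise: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gaussian expression profiles around per-cluster centroids.

    A convenience generator for exercising the k-means path: cluster ``c``
    gets a centroid drawn once at scale ``separation``, and each gene's
    profile is its centroid plus N(0, noise^2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels, int)
    k = labels.max()
    centroids = rng.normal(0.0, separation, size=(k, n_conditions))
    x = centroids[labels - 1] + rng.normal(0.0, noise, size=(labels.size, n_conditions))
    return pd.DataFrame(
        x,
        index=[f"gene{i:04d}" for i in range(labels.size)],
        columns=[f"cond{j}" for j in range(n_conditions)],
    )


def _default_init(dataset: SimDataset, weight: float, use_sequence: bool = True) -> ModelParams:
    """Neutral EM starting point: stationary-ish rates, mid q, near-uniform
    thetas with a slight tilt so theta1 and theta0 can separate."""
    species = dataset.species
    k = dataset.scenario.k_clusters
    tilt = np.linspace(1.1, 0.9, k)
    theta1 = {sp: tilt / tilt.sum() for sp in species}
    theta0 = {sp: np.full(k, 1.0 / k) for sp in species}
    return ModelParams(
        rates=RateParams(lam=0.5, mu=0.5, pi_root=0.5),
        seq=SequenceModelParams(q=0.005),
        expr=ExpressionParams(theta0=theta0, theta1=theta1),
        weight=weight,
        use_sequence=use_sequence,
    )


def crossvalidate(
    dataset: SimDataset,
    k_folds: int = 5,
    weight_grid: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 5.0),
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: ModelParams | None = None,
) -> pd.DataFrame:
    """K-fold cross-validation over an expression-weight grid.

    Groups are partitioned into seeded folds; for each weight the model is
    fit on k-1 folds and the held-out fold's states are inferred with the
    fitted parameters and scored against the hidden truth.  Returns one row
    per (weight, fold) with train and test accuracy.
    """
    m = dataset.m
    if k_folds > m:
        raise ValueError("more folds than groups")
    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    folds = np.array_split(perm, k_folds)
    if any(f.size < 1 for f in folds):
        raise ValueError("empty fold")
    groups_all = groups_from_windows(
        dataset.windows, dataset.labels, dataset.pssm, SequenceModelParams()
    )
    tree = dataset.scenario.tree
    rows = []
    for weight in weight_grid:
        base_init = init if init is not None else _default_init(dataset, weight)
        base_init = replace(base_init, weight=float(weight))
        for fold_i, test_idx in enumerate(folds):
            test_set = set(test_idx.tolist())
            train = [g for i, g in enumerate(groups_all) if i not in test_set]
            test = [groups_all[i] for i in sorted(test_set)]
            fit = em_fit(train, tree, base_init, max_iter=max_iter, tol=tol)
            train_truth = [dataset.truth[i] for i in range(m) if i not in test_set]
            test_truth = [dataset.truth[i] for i in sorted(test_set)]
            train_acc = prediction_accuracy(infer_states(train, tree, fit.params), train_truth)
            test_acc = prediction_accuracy(infer_states(test, tree, fit.params), test_truth)
            rows.append(
                {
                    "weight": float(weight),
                    "fold": fold_i,
                    "train_accuracy": train_acc,
                    "test_accuracy": test_acc,
                    "loglik": fit.loglik,
                }
            )
    return pd.DataFrame(rows)
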