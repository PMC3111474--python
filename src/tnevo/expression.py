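"""Expression preprocessing and the conditional expression likelihood P(E | Z).

Expression enters the model "softly": per-species expression matrices are
clustered, and the model only sees each gene's cluster index.  Target genes
(Z=1) concentrate in a subset of clusters, so the cluster index follows a
target multinomial theta1; non-targets follow a background multinomial
theta0.  Cluster numbers K may differ across species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ExpressionClustering",
    "ExpressionParams",
    "filter_by_cv",
    "kmeans_cluster",
    "estimate_multinomial",
    "expr_loglik",
]


@dataclass(frozen=True)
class ExpressionClustering:
    """Per-species clustering: gene -> cluster label in 1..K."""

    species: str
    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        bad = {g: c for g, c in self.labels.items() if not (1 <= c <= self.k)}
        if bad:
            raise ValueError(f"labels outside 1..{self.k}: {bad}")

    @property
    def singletons(self) -> set[str]:
        """Genes alone in their cluster (dropped from model fitting)."""
        counts = pd.Series(list(self.labels.values())).value_counts()
        lonely = set(counts[counts == 1].index)
        return {g for g, c in self.labels.items() if c in lonely}


@dataclass(frozen=True)
class ExpressionParams:
    """Per-species background (theta0) and target (theta1) cluster multinomials."""

    theta0: dict[str, np.ndarray]
    theta1: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.theta0) != set(self.theta1):
            raise ValueError("theta0 and theta1 must cover the same species")
        for which, thetas in (("theta0", self.theta0), ("theta1", self.theta1)):
            for sp, th in thetas.items():
                th = np.asarray(th, float)
                thetas[sp] = th
                if not np.isclose(th.sum(), 1.0, atol=1e-9):
                    raise ValueError(f"{which}[{sp}] must sum to 1")
                if np.any(th <= 0):
                    raise ValueError(f"{which}[{sp}] must be strictly positive")

    @property
    def species(self) -> list[str]:
        return sorted(self.theta0)

    def k(self, species: str) -> int:
        return self.theta0[species].size


def filter_by_cv(
    matrices: Mapping[str, pd.DataFrame],
    ortholog_map: pd.DataFrame,
    threshold: float = 1.26,
) -> list:
    """Keep ortholog groups with a clear expression change in some species.

    A group is retained iff at least one member gene's coefficient of
    variation (sd/mean across conditions) exceeds ``threshold``.  The default
    1.26 is the mammalian preprocessing cut.  ``ortholog_map`` is indexed by
    group id with one gene-id column per species.  Genes with zero mean get
    CV 0 with a warning.
    """
    cvs: dict[str, pd.Series] = {}
    for sp in ortholog_map.columns:
        mat = matrices[sp]
        if mat.shape[1] < 2:
            raise ValueError(f"species {sp}: need >= 2 conditions for a CV")
        if (mat.values < 0).any():
            raise ValueError(f"species {sp}: expression values must be nonnegative")
        mean = mat.mean(axis=1)
        sd = mat.std(axis=1, ddof=1)
        zero = mean == 0
        if zero.any():
            warnings.warn(
                f"species {sp}: {int(zero.sum())} zero-mean genes treated as CV=0",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = sd / mean
        cv[zero] = 0.0
        cvs[sp] = cv
    keep = []
    for gid, row in ortholog_map.iterrows():
        group_cvs = [cvs[sp].get(row[sp], 0.0) for sp in ortholog_map.columns]
        if max(group_cvs) > threshold:
            keep.append(gid)
    return keep


def kmeans_cluster(
    expr_matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    species: str = "species",
    standardize: bool = True,
) -> ExpressionClustering:
    """Cluster genes (rows) by expression profile with seeded k-means.

    Profiles are z-scored per gene across conditions before clustering so
    that profile shape, not level, drives membership; constant profiles map
    to the zero vector.  Labels are 1..k and deterministic given the seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > expr_matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({expr_matrix.shape[0]})")
    x = expr_matrix.to_numpy(dtype=float)
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x) + 1
    return ExpressionClustering(
        species=species,
        labels=dict(zip(expr_matrix.index.astype(str), (int(c) for c in labels))),
        k=k,
    )


def estimate_multinomial(
    labels: Sequence[int],
    weights: Sequence[float],
    k: int,
    smoothing: float = 0.5,
) -> np.ndarray:
    """Weighted multinomial over cluster indices: theta[c] ~ smoothing + sum of
    the weights of genes labeled c, normalized.  All-zero weights fall back
    to uniform with a warning."""
    labels = np.asarray(labels, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if labels.shape != weights.shape:
        raise ValueError("labels and weights must align")
    if np.any((weights < 0) | (weights > 1)):
        raise ValueError("weights must lie in [0, 1]")
    if np.any((labels < 1) | (labels > k)):
        raise ValueError(f"labels must lie in 1..{k}")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    counts = np.bincount(labels - 1, weights=weights, minlength=k) + smoothing
    total = counts.sum()
    if total == 0:
        warnings.warn("all weights zero and no smoothing; returning uniform", stacklevel=2)
        return np.full(k, 1.0 / k)
    return counts / total


def expr_loglik(label: int, z: int, params: ExpressionParams, species: str) -> float:
    """log P(cluster label | Z=z) = log theta_z[label] for the given species."""
    if z not in (0, 1):
        raise ValueError("z must be 0 or 1")
    theta = (params.theta1 if z == 1 else params.theta0)[species]
    if not (1 <= label <= theta.size):
        raise ValueError(f"label {label} outside 1..{theta.size} for species {species}")
    return float(np.log(theta[label - 1]))
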