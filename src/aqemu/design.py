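"""Space-filling scenario designs for emulator training and testing.

A scenario is a vector of five sector scaling factors in [0, 1.5]
(1.0 = the baseline year). Training/test designs are maximin Latin
hypercubes: among ``n_candidates`` Latin hypercube samples the one with the
largest minimum pairwise distance is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .synthetic import SECTORS


@dataclass
class DesignMatrix:
    """An ordered set of emission scenarios with a train/test role tag."""

    X: np.ndarray  # (n_runs, n_dims), already scaled to [lower, upper]
    role: str = "train"
    seed: int | None = None
    lower: float = 0.0
    upper: float = 1.5

    @property
    def n_runs(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = SECTORS if self.X.shape[1] == len(SECTORS) else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        return pd.DataFrame(self.X, columns=list(cols))


def _min_distance(X: np.ndarray) -> float:
    if X.shape[0] < 2:
        return np.inf
    return float(pdist(X).min())


def maximin_lhs(
    n_runs: int,
    n_dims: int = len(SECTORS),
    lower: float = 0.0,
    upper: float = 1.5,
    n_candidates: int = 100,
    seed: int = 0,
    role: str = "train",
    midpoints: bool = False,
) -> DesignMatrix:
    """Candidate-search maximin Latin hypercube design.

    Each of ``n_candidates`` candidates is a Latin hypercube (every
    dimension stratified into ``n_runs`` equal bins, each bin sampled
    once); the candidate maximizing the minimum pairwise Euclidean distance
    wins, first candidate on ties. Candidates are drawn from a single
    seeded stream, so the search is deterministic and nested in
    ``n_candidates``. ``midpoints=True`` centres points in their strata.
    """
    if n_runs < 1 or n_candidates < 1 or n_dims < 1:
        raise ValueError("counts must be positive")
    if not lower < upper:
        raise ValueError("need lower < upper")
    sampler = qmc.LatinHypercube(
        d=n_dims, scramble=not midpoints, seed=np.random.default_rng(seed)
    )
    best, best_score = None, -np.inf
    for _ in range(n_candidates):
        cand = sampler.random(n_runs)
        score = _min_distance(cand)
        if score > best_score:
            best, best_score = cand, score
    X = qmc.scale(best, lower, upper)
    return DesignMatrix(X=X, role=role, seed=seed, lower=lower, upper=upper)


def train_test_designs(
    n_train: int = 50,
    n_test: int = 5,
    seeds: tuple[int, int] = (0, 1),
    n_dims: int = len(SECTORS),
    lower: float = 0.0,
    upper: float = 1.5,
    n_candidates: int = 100,
) -> tuple[DesignMatrix, DesignMatrix]:
    """Two independent maximin LHS designs tagged train and test."""
    if seeds[0] == seeds[1]:
        raise ValueError("train and test designs require distinct seeds")
    train = maximin_lhs(
        n_train, n_dims, lower, upper, n_candidates, seed=seeds[0], role="train"
    )
    test = maximin_lhs(
        n_test, n_dims, lower, upper, n_candidates, seed=seeds[1], role="test"
    )
    return train, test
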