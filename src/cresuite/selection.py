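"""Representative element selection by facility-location maximization.

Given a nonnegative symmetric similarity matrix phi over a ground set V, the
facility-location objective of a subset A is

    f(A) = sum over v in V of max over a in A of phi(v, a),

a monotone submodular function whose greedy maximization carries the classic
(1 - 1/e) approximation guarantee. Similarities are built from element
feature vectors via the Pearson correlation coefficient mapped to [0, 1].
The optimizer is a lazy greedy (priority-queue) implementation that is
exactly equivalent to naive greedy under the fixed tie-break (largest gain,
then smallest element id); an exhaustive optimizer serves as an oracle on
small instances. A stratified equal-width activity-bin sampler supports
joint-library style designs.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "similarity_from_features",
    "facility_location_value",
    "greedy_select",
    "naive_greedy_select",
    "exhaustive_select",
    "stratified_bin_sample",
]


def similarity_from_features(
    features: pd.DataFrame, mapping: str = "shift"
) -> pd.DataFrame:
    """Pairwise Pearson similarity between element feature vectors.

    ``mapping`` turns correlations nonnegative: ``"shift"`` uses (r + 1) / 2
    (default), ``"clip"`` uses max(r, 0). The diagonal is 1. Constant feature
    vectors have no defined correlation and raise an error naming the element.
    """
    if features.shape[1] < 2:
        raise ValueError("need >= 2 features per element")
    x = features.to_numpy(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(features.index[sd == 0])
        raise ValueError(f"constant feature vector for element(s): {bad[:5]}")
    r = np.corrcoef(x)
    if mapping == "shift":
        sim = (r + 1.0) / 2.0
    elif mapping == "clip":
        sim = np.maximum(r, 0.0)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=features.index, columns=features.index)


def _as_matrix(sim: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(sim, pd.DataFrame):
        return sim.to_numpy(float), list(sim.index)
    arr = np.asarray(sim, dtype=float)
    return arr, list(range(arr.shape[0]))


def _validate_similarity(mat: np.ndarray) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("similarity matrix must be square")
    if (mat < 0).any():
        raise ValueError("similarities must be nonnegative")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")


def facility_location_value(
    sim: pd.DataFrame | np.ndarray, selected: Sequence
) -> float:
    """Exact objective: sum over the ground set of row maxima over ``selected``."""
    mat, ids = _as_matrix(sim)
    _validate_similarity(mat)
    if len(selected) == 0:
        raise ValueError("selected set must be non-empty")
    pos = {e: i for i, e in enumerate(ids)}
    try:
        cols = [pos[e] for e in selected]
    except KeyError as err:
        raise ValueError(f"unknown element id {err.args[0]!r}") from None
    return float(mat[:, cols].max(axis=1).sum())


@dataclass
class SelectionResult:
    """Greedy facility-location selection with its marginal-gain trace."""

    selected: list
    gains: list[float]
    objective: float

    @property
    def k(self) -> int:
        return len(self.selected)


def greedy_select(sim: pd.DataFrame | np.ndarray, k: int) -> SelectionResult:
    """Lazy-greedy facility-location maximization.

    Cached marginal gains are kept in a max-heap and re-evaluated only when
    they surface (valid because submodularity makes gains non-increasing);
    ties break toward the smaller element index / ascending id. The output
    is identical to naive greedy under the same tie-break.
    """
    mat, ids = _as_matrix(sim)
    _validate_similarity(mat)
    n = mat.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    covered = np.zeros(n)  # current max similarity per ground element
    heap = [(-float(mat[:, j].sum()), j) for j in range(n)]
    heapq.heapify(heap)
    selected: list[int] = []
    gains: list[float] = []
    in_set = np.zeros(n, dtype=bool)
    while len(selected) < k:
        neg_cached, j = heapq.heappop(heap)
        if in_set[j]:
            continue
        fresh = float(np.maximum(mat[:, j] - covered, 0.0).sum())
        # cached gains are upper bounds (submodularity); an entry whose cache
        # is still current dominates every other cache and hence every other
        # fresh gain, and heap order (-gain, index) realizes the tie-break.
        # Exact float comparison: recomputation is deterministic, so a
        # current cache reproduces bit-identically.
        if heap and fresh != -neg_cached:
            heapq.heappush(heap, (-fresh, j))
            continue
        selected.append(j)
        gains.append(fresh)
        in_set[j] = True
        covered = np.maximum(covered, mat[:, j])
    return SelectionResult(
        selected=[ids[j] for j in selected],
        gains=gains,
        objective=float(covered.sum()),
    )


def naive_greedy_select(sim: pd.DataFrame | np.ndarray, k: int) -> SelectionResult:
    """Reference greedy: recompute every marginal gain at every step."""
    mat, ids = _as_matrix(sim)
    _validate_similarity(mat)
    n = mat.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    covered = np.zeros(n)
    selected: list[int] = []
    gains: list[float] = []
    remaining = list(range(n))
    for _ in range(k):
        best_j, best_gain = None, -np.inf
        for j in remaining:
            gain = float(np.maximum(mat[:, j] - covered, 0.0).sum())
            if gain > best_gain:  # exact: ties keep the smallest index
                best_j, best_gain = j, gain
        selected.append(best_j)
        gains.append(best_gain)
        remaining.remove(best_j)
        covered = np.maximum(covered, mat[:, best_j])
    return SelectionResult(
        selected=[ids[j] for j in selected],
        gains=gains,
        objective=float(covered.sum()),
    )


def exhaustive_select(
    sim: pd.DataFrame | np.ndarray, k: int, max_combinations: int = 10**6
) -> tuple[list, float]:
    """Brute-force optimal subset (oracle for small instances).

    Ties break toward the lexicographically smallest index tuple. Refuses
    instances with more than ``max_combinations`` candidate subsets.
    """
    mat, ids = _as_matrix(sim)
    _validate_similarity(mat)
    n = mat.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if math.comb(n, k) > max_combinations:
        raise ValueError(f"C({n},{k}) exceeds {max_combinations} subsets")
    best_set, best_val = None, -np.inf
    for combo in combinations(range(n), k):
        val = float(mat[:, combo].max(axis=1).sum())
        if val > best_val + 1e-12:
            best_set, best_val = combo, val
    return [ids[j] for j in best_set], best_val


def stratified_bin_sample(
    scores: pd.Series, n_total: int, n_bins: int = 10, seed: int = 0
) -> list:
    """Sample ids approximately uniformly across equal-width score bins.

    Bins span [min, max] of ``scores``; each bin's quota is n_total / n_bins,
    with deficits from sparse bins redistributed to the bins with the most
    remaining elements. A degenerate score range collapses to a single bin
    with a warning. Deterministic under ``seed``.
    """
    scores = scores.dropna()
    if n_total > len(scores):
        raise ValueError("n_total exceeds the number of elements")
    lo, hi = float(scores.min()), float(scores.max())
    if lo == hi:
        warnings.warn("degenerate score range; sampling from a single bin", stacklevel=2)
        n_bins = 1
        bins = np.zeros(len(scores), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(scores.to_numpy(), edges[1:-1]), 0, n_bins - 1)
    rng = np.random.default_rng([seed, 4])
    members = {b: list(scores.index[bins == b]) for b in range(n_bins)}
    quota = {b: n_total // n_bins for b in range(n_bins)}
    for b in range(n_total % n_bins):
        quota[b] += 1
    # give sparse bins everything they have; redistribute to fullest bins
    taken = {b: min(quota[b], len(members[b])) for b in range(n_bins)}
    deficit = n_total - sum(taken.values())
    while deficit > 0:
        spare = {b: len(members[b]) - taken[b] for b in range(n_bins)}
        b = max(spare, key=lambda b: (spare[b], -b))
        if spare[b] <= 0:
            raise RuntimeError("redistribution failed")  # unreachable: n_total <= n
        taken[b] += 1
        deficit -= 1
    sampled: list = []
    for b in range(n_bins):
        if taken[b] == 0:
            continue
        idx = rng.choice(len(members[b]), size=taken[b], replace=False)
        sampled.extend(members[b][i] for i in sorted(idx))
    return sampled
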