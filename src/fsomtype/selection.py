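"""Light-weight consensus procedure for choosing the number of clusters.

Full consensus clustering re-clusters many perturbed data sets for every
candidate k, which is prohibitive when each clustering run needs
DTW-based SOM training.  The light-weight variant trains a *single*
partition with M mediods (the prototypes of an FSOM with M neurons),
records each item's ranking of all mediods by normalized DTW distance,
and then, for every k, repeatedly samples k-subsets of mediods and
re-assigns every item to its best-ranked mediod inside the subset —
no further distance computations.  Co-assignment frequencies across the
m subset draws form the consensus matrix for k; the area under the
empirical CDF of its entries summarizes partition stability, and the
selected k* is the largest k whose area still shows a relative increase
of at least ``delta_min`` over k-1 (the proportional-increase rule of
the consensus-clustering framework).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dtw import dtw_distance
from .profiles import Profile
from .som import init_grid, train

__all__ = ["MediodRanking", "ConsensusSelection", "near_square_grid",
           "build_mediods", "consensus_for_k", "cdf_area", "select_k_star",
           "select_k"]


@dataclass
class MediodRanking:
    """Per item, all M mediods ordered by increasing normalized DTW."""

    mediods: list[np.ndarray]
    ranking: np.ndarray  # (n_items, M) mediod indices, best first
    item_ids: list[str]

    @property
    def n_mediods(self) -> int:
        return len(self.mediods)


@dataclass
class ConsensusSelection:
    """Consensus matrices, CDF areas and the selected number of clusters."""

    areas: dict[int, float]
    deltas: dict[int, float]
    k_star: int
    n_subsamples: int
    seed: int
    consensus: dict[int, np.ndarray] = field(default_factory=dict)


def near_square_grid(M: int) -> tuple[int, int]:
    """Factor M into the most nearly square rows x cols grid."""
    rows = int(math.isqrt(M))
    while M % rows:
        rows -= 1
    return rows, M // rows


def _check_condition(M: int, k_range, m: int) -> None:
    for k in k_range:
        if math.comb(M, k) < m:
            M_min = M
            while any(math.comb(M_min, kk) < m for kk in k_range):
                M_min += 1
            raise ValueError(
                f"C(M={M}, k={k}) = {math.comb(M, k)} < m={m}; "
                f"need M >= {M_min} for {m} distinct mediod subsets")


def build_mediods(profiles: list[Profile], M: int, seed: int = 0,
                  k_min: int = 4, K: int = 8, m: int = 50,
                  **som_kw) -> MediodRanking:
    """Train one M-neuron FSOM and rank its prototypes per item.

    The single M-group partition supplies the mediods (trained
    prototypes, row-major grid order); each item's ranking is the
    permutation of mediod indices by increasing normalized DTW distance,
    ties broken by mediod index.
    """
    if M < K:
        raise ValueError(f"M={M} must be at least K={K}")
    _check_condition(M, range(k_min, K + 1), m)
    rows, cols = near_square_grid(M)
    grid = init_grid(rows, cols, profiles, seed=seed, **som_kw)
    grid, _ = train(grid, profiles)
    mediods = [n.weights.copy() for n in grid.neurons]
    n = len(profiles)
    dist = np.empty((n, M))
    for a, p in enumerate(profiles):
        for b, w in enumerate(mediods):
            dist[a, b] = dtw_distance(p.values, w, grid.band_radius)
    ranking = np.argsort(dist, axis=1, kind="stable")
    return MediodRanking(mediods=mediods, ranking=ranking,
                         item_ids=[p.event_id for p in profiles])


def consensus_for_k(rankings: MediodRanking, k: int, m: int,
                    seed: int = 0) -> np.ndarray:
    """Consensus matrix from m distinct k-subsets of mediods.

    Every item is assigned to its highest-ranked mediod within each
    sampled subset, using only the stored rankings (no DTW).  Entry
    (a, b) is the fraction of the m draws in which items a and b share
    an assignment.
    """
    M = rankings.n_mediods
    _check_condition(M, [k], m)
    rng = np.random.default_rng(seed)
    n = rankings.ranking.shape[0]
    # rank position of each mediod per item (inverse permutation)
    pos = np.empty_like(rankings.ranking)
    rows = np.arange(n)[:, None]
    pos[rows, rankings.ranking] = np.arange(M)[None, :]
    seen: set[tuple] = set()
    consensus = np.zeros((n, n))
    while len(seen) < m:
        subset = tuple(sorted(rng.choice(M, size=k, replace=False).tolist()))
        if subset in seen:
            continue
        seen.add(subset)
        sub = np.array(subset)
        labels = sub[np.argmin(pos[:, sub], axis=1)]
        consensus += labels[:, None] == labels[None, :]
    return consensus / m


def cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle entries.

    The CDF is the step function over entry values in [0, 1]; the area
    is the sum of CDF(x_i) * (x_{i+1} - x_i) over the sorted unique
    values (with the interval closed at 1).  Low areas mean most pairs
    always co-cluster; high areas mean most pairs never do.
    """
    n = consensus.shape[0]
    if n < 2:
        raise ValueError("consensus matrix needs at least 2 items")
    vals = consensus[np.triu_indices(n, k=1)]
    xs, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / vals.shape[0]
    edges = np.append(xs, 1.0)
    return float(np.sum(cdf * np.diff(edges)))


def select_k_star(areas: dict[int, float], delta_min: float = 0.025,
                  k_min: int | None = None) -> tuple[int, dict[int, float]]:
    """Pick k* from CDF areas by the proportional-increase rule.

    Delta(k_min) = A(k_min); Delta(k) = (A(k) - A(k-1)) / A(k-1) for
    larger k.  k* is the largest k whose Delta is at least ``delta_min``;
    if no k beyond k_min qualifies, k* = k_min.
    """
    ks = sorted(areas)
    if k_min is None:
        k_min = ks[0]
    if ks != list(range(k_min, ks[-1] + 1)):
        raise ValueError(f"areas must cover a contiguous k range, got {ks}")
    deltas = {k_min: areas[k_min]}
    for k in ks[1:]:
        prev = areas[k - 1]
        deltas[k] = (areas[k] - prev) / prev if prev > 0 else math.inf
    qualifying = [k for k in ks if deltas[k] >= delta_min]
    k_star = max(qualifying) if qualifying else k_min
    return k_star, deltas


def select_k(profiles: list[Profile], K: int = 8, m: int = 50,
             M: int | None = None, seed: int = 0, k_min: int = 4,
             delta_min: float = 0.025, keep_consensus: bool = False,
             **som_kw) -> ConsensusSelection:
    """End-to-end light-weight selection of the number of clusters.

    ``M`` defaults to 2 K (raised if needed so that C(M, k) >= m for
    every scanned k).  Sub-seeds for the base partition and for each
    k's subset sampling are derived from ``seed``.
    """
    if M is None:
        M = 2 * K
        while any(math.comb(M, k) < m for k in range(k_min, K + 1)):
            M += 1
    ss = np.random.SeedSequence(seed).spawn(K - k_min + 2)
    base_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    rankings = build_mediods(profiles, M, seed=base_seed, k_min=k_min,
                             K=K, m=m, **som_kw)
    areas, consensus = {}, {}
    for idx, k in enumerate(range(k_min, K + 1)):
        sk = int(ss[idx + 1].generate_state(1)[0] % (2 ** 31))
        C = consensus_for_k(rankings, k, m, seed=sk)
        areas[k] = cdf_area(C)
        if keep_consensus:
            consensus[k] = C
    k_star, deltas = select_k_star(areas, delta_min, k_min)
    return ConsensusSelection(areas=areas, deltas=deltas, k_star=k_star,
                              n_subsamples=m, seed=seed, consensus=consensus)
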