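"""Flexible self-organizing map (FSOM) over variable-length profiles.

A classical SOM averages each input into the prototypes near its best
matching unit (BMU).  That breaks down when inputs have different
lengths and the similarity is dynamic time warping: averaging along the
warping path repeatedly would twist the prototype through interpolation.
The FSOM strategy instead

* moves prototype *values* toward the warped input along the optimal
  path, and
* accumulates the *length* pressure (path steps where the prototype is
  locally under- or over-long relative to the input) per prototype
  element; only when an element's accumulator reaches an integer-valued
  threshold is a single one-element insertion (interpolating its new
  neighbors) or deletion (merging with the successor) triggered, after
  which the accumulator resets.

Prototype lengths therefore track the typical input length without
per-iteration interpolation noise.

Normalized mutual information (NMI) is provided for validating the
agreement between two clusterings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dtw import dtw, dtw_distance
from .profiles import Profile

__all__ = ["Neuron", "SOMGrid", "init_grid", "find_bmu", "adjust_neuron",
           "train", "nmi"]


@dataclass
class Neuron:
    """One grid unit: a variable-length prototype with shift accumulators."""

    row: int
    col: int
    weights: np.ndarray
    acc: np.ndarray  # per-element accumulated length-adjustment pressure

    def copy(self) -> "Neuron":
        return Neuron(self.row, self.col, self.weights.copy(), self.acc.copy())


@dataclass
class SOMGrid:
    """Grid of neurons plus the training hyperparameters.

    ``alpha0``/``alphaT`` and ``sigma0``/``sigmaT`` are the initial and
    final learning rate and neighborhood radius; both decay
    exponentially over the epochs.  ``theta`` is the accumulator
    threshold that gates prototype length changes; ``band_radius`` the
    DTW band (bins).
    """

    rows: int
    cols: int
    neurons: list[Neuron]
    epochs: int = 30
    alpha0: float = 0.5
    alphaT: float = 0.01
    sigma0: float | None = None   # default max(rows, cols) / 2
    sigmaT: float = 0.5
    theta: float = 1.0
    band_radius: float | None = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.theta < 1:
            raise ValueError("accumulator threshold theta must be >= 1")
        if self.sigma0 is None:
            self.sigma0 = max(self.rows, self.cols) / 2.0

    def neuron(self, row: int, col: int) -> Neuron:
        return self.neurons[row * self.cols + col]


def init_grid(rows: int, cols: int, profiles: list[Profile], seed: int = 0,
              **hyper) -> SOMGrid:
    """Initialize prototypes as copies of distinct sampled input profiles."""
    k = rows * cols
    if len(profiles) < k:
        raise ValueError(
            f"need at least {k} profiles to initialize a {rows}x{cols} grid, "
            f"got {len(profiles)}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(profiles), size=k, replace=False)
    neurons = []
    for idx, flat in enumerate(picks):
        w = np.asarray(profiles[flat].values, dtype=float).copy()
        neurons.append(Neuron(idx // cols, idx % cols, w, np.zeros(w.shape[0])))
    return SOMGrid(rows=rows, cols=cols, neurons=neurons, seed=seed, **hyper)


def find_bmu(grid: SOMGrid, values: np.ndarray) -> tuple[Neuron, float]:
    """Neuron with minimal normalized DTW distance (ties: row-major order)."""
    best, best_d = None, math.inf
    for neuron in grid.neurons:  # row-major
        d = dtw_distance(values, neuron.weights, grid.band_radius)
        if d < best_d:
            best, best_d = neuron, d
    return best, best_d


def adjust_neuron(neuron: Neuron, values: np.ndarray, alpha: float,
                  theta: float, band_radius: float | None = None) -> None:
    """Pull one prototype toward an input along the optimal warping path.

    Mechanics (in order):

    1. the optimal (banded) warping path P between the input S = (x_i)
       and the prototype W = (y_j) is computed;
    2. every Shrinking step of P (S advances, W holds: W locally
       under-long) adds ``+alpha`` to the held element's accumulator,
       every Expansion step (W advances, S holds: W locally over-long)
       adds ``-alpha`` to the newly consumed element's accumulator;
    3. accumulators at or beyond ``theta`` in magnitude trigger a length
       change: a positive trigger inserts one element after position j,
       valued as the linear interpolation of its new neighbors, and the
       surplus path matches of j are handed to the inserted element; a
       negative trigger merges element j with its successor as their
       average (suppressed if W would drop below 2 elements).  Indices
       above j shift accordingly, their accumulators unchanged; the
       triggering accumulator resets to 0;
    4. value update: each prototype element moves toward the mean of the
       input values matched to it, ``y' = y + alpha * (mean(x) - y)``
       (multiply-matched elements are averaged before the single update,
       so the result does not depend on match order).

    With ``theta = inf`` and equal-length inputs whose optimal path is
    the diagonal this reduces exactly to the classical SOM update.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha == 0.0:
        return
    x = np.asarray(values, dtype=float)
    res = dtw(x, neuron.weights, band_radius)
    pairs = res.path.pairs
    m = neuron.weights.shape[0]
    matches: list[list[float]] = [[] for _ in range(m)]
    for i, j in pairs:
        matches[j].append(x[i])
    acc = list(neuron.acc)
    wts = list(neuron.weights)
    for k in range(pairs.shape[0] - 1):
        di = pairs[k + 1, 0] - pairs[k, 0]
        dj = pairs[k + 1, 1] - pairs[k, 1]
        if di == 1 and dj == 0:      # shrinking: W under-long at j_k
            acc[pairs[k, 1]] += alpha
        elif di == 0 and dj == 1:    # expansion: W over-long at j_{k+1}
            acc[pairs[k + 1, 1]] -= alpha
    # process triggers right-to-left so earlier indices stay valid
    for j in range(m - 1, -1, -1):
        if acc[j] >= theta:
            left = wts[j]
            right = wts[j + 1] if j + 1 < len(wts) else wts[j]
            wts.insert(j + 1, (left + right) / 2.0)
            acc.insert(j + 1, 0.0)
            matches.insert(j + 1, matches[j][1:])
            matches[j] = matches[j][:1]
            acc[j] = 0.0
        elif acc[j] <= -theta:
            if len(wts) > 2:
                jj = j if j + 1 < len(wts) else j - 1
                wts[jj] = (wts[jj] + wts[jj + 1]) / 2.0
                del wts[jj + 1]
                matches[jj] = matches[jj] + matches[jj + 1]
                del matches[jj + 1]
                del acc[jj + 1]
                acc[jj] = 0.0
            else:
                acc[j] = 0.0  # deletion suppressed: W already minimal
    w = np.array(wts)
    for j, xs in enumerate(matches):
        if xs:
            w[j] += alpha * (float(np.mean(xs)) - w[j])
    neuron.weights = w
    neuron.acc = np.array(acc)


def _schedule(v0: float, vT: float, t: int, T: int) -> float:
    return v0 * (vT / v0) ** (t / T)


def train(grid: SOMGrid, profiles: list[Profile],
          epochs: int | None = None) -> tuple[SOMGrid, dict[str, tuple[int, int]]]:
    """Train the grid and return final BMU assignments.

    Per epoch the profiles are visited in a seeded shuffled order; for
    each input the BMU is found and every neuron within grid Chebyshev
    distance r <= ceil(sigma(t)) of it is adjusted with force
    ``alpha(t) * exp(-r^2 / (2 sigma(t)^2))``; alpha and sigma decay
    exponentially from their initial to final values over the epochs.
    The DTW path is recomputed per adjusted neuron.  Training mutates
    and returns the grid; assignments map event_id -> (row, col) of the
    final BMU.
    """
    T = epochs if epochs is not None else grid.epochs
    if T < 1:
        raise ValueError("need at least one training epoch")
    rng = np.random.default_rng(grid.seed)
    for t in range(T):
        alpha_t = _schedule(grid.alpha0, grid.alphaT, t, T)
        sigma_t = _schedule(grid.sigma0, grid.sigmaT, t, T)
        h = math.ceil(sigma_t)
        for idx in rng.permutation(len(profiles)):
            values = profiles[idx].values
            bmu, _ = find_bmu(grid, values)
            for neuron in grid.neurons:
                r = max(abs(neuron.row - bmu.row), abs(neuron.col - bmu.col))
                if r <= h:
                    force = alpha_t * math.exp(-(r * r) / (2.0 * sigma_t ** 2))
                    adjust_neuron(neuron, values, force, grid.theta,
                                  grid.band_radius)
    assignments = {}
    for p in profiles:
        bmu, _ = find_bmu(grid, p.values)
        assignments[p.event_id] = (bmu.row, bmu.col)
    return grid, assignments


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Uses the arithmetic-mean normalization 2 I(A;B) / (H(A) + H(B)).
    Identical partitions (up to label renaming) score 1.0, independent
    partitions 0.0.  When both partitions are a single cluster the
    agreement is perfect and the score is defined as 1.0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be equal-length 1-d sequences")
    n = a.shape[0]
    if n == 0:
        raise ValueError("empty labelings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(cont, (ai, bi), 1.0)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    ha = -sum(p * math.log(p) for p in pi if p > 0)
    hb = -sum(p * math.log(p) for p in pj if p > 0)
    if ha == 0.0 and hb == 0.0:
        return 1.0
    hab = -sum(p * math.log(p) for p in pij.ravel() if p > 0)
    mi = ha + hb - hab  # I(A;B) = H(A) + H(B) - H(A,B)
    val = 2.0 * mi / (ha + hb)
    return min(max(val, 0.0), 1.0)
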