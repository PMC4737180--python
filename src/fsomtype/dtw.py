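"""Dynamic time warping between methylation profiles.

DTW aligns two real-valued sequences with a monotone, continuous and
bounded warping path and scores the alignment by the summed squared
difference of the matched values.  It is the similarity measure used
throughout this package because methylation profiles of functionally
similar splice-site regions can be locally stretched, shrunk or shifted
(unequal exon/intron lengths), which a position-wise distance cannot
absorb.

The optimal path is found by dynamic programming; an optional
Sakoe-Chiba-style band restricts the path to a corridor around the
(slope-adjusted) diagonal, which both speeds up the computation and
excludes pathological alignments.  Costs are additionally reported
normalized by the number of path nodes so that sequences of different
lengths are comparable.

DTW is symmetric but does *not* obey the triangle inequality; it is a
dissimilarity, not a metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["WarpingPath", "DTWResult", "BandError", "dtw", "dtw_distance",
           "pairwise_distances", "min_feasible_radius"]


class BandError(ValueError):
    """Raised when a Sakoe-Chiba band admits no valid warping path.

    Attributes
    ----------
    min_radius : float
        The smallest band radius (in bins) for which a monotone,
        continuous, bounded path exists for the offending pair of
        sequence lengths.
    """

    def __init__(self, n: int, m: int, radius: float, min_radius: float):
        self.min_radius = min_radius
        super().__init__(
            f"band radius {radius} admits no warping path for lengths "
            f"({n}, {m}); minimal feasible radius is {min_radius}"
        )


@dataclass(frozen=True)
class WarpingPath:
    """Monotone, continuous, bounded alignment between two sequences."""

    pairs: np.ndarray  # (L, 2) int array of (i, j) index pairs

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.pairs))


@dataclass(frozen=True)
class DTWResult:
    """Optimal warping path with raw and path-length-normalized cost."""

    cost: float
    normalized: float
    path: WarpingPath
    band_radius: float | None


def _band_bounds(n: int, m: int, radius: float | None):
    """Per-row admissible column interval [lo[i], hi[i]] of the band.

    The band is slope-adjusted: |i*(m-1)/(n-1) - j| <= radius, so the
    bounding endpoints (0,0) and (n-1,m-1) always lie on its center line
    even for unequal lengths.
    """
    if radius is None or radius >= max(n, m):
        lo = np.zeros(n, dtype=np.int64)
        hi = np.full(n, m - 1, dtype=np.int64)
        return lo, hi
    slope = (m - 1) / (n - 1) if n > 1 else 0.0
    centers = np.arange(n) * slope
    lo = np.maximum(np.ceil(centers - radius), 0).astype(np.int64)
    hi = np.minimum(np.floor(centers + radius), m - 1).astype(np.int64)
    return lo, hi


def _band_feasible(lo: np.ndarray, hi: np.ndarray, m: int) -> bool:
    """Check that some monotone/continuous path survives the band."""
    n = lo.shape[0]
    if lo[0] > 0 or hi[-1] < m - 1:
        return False
    # Reachable columns in each row form an interval [a, hi[i]]: within a
    # row horizontal steps may extend right; row transitions move j by 0/1.
    a = 0
    for i in range(1, n):
        if np.any(lo[i] > hi[i]):
            return False
        if a > hi[i] or hi[i - 1] + 1 < lo[i]:
            return False
        a = max(a, lo[i])
    return a <= m - 1


def min_feasible_radius(n: int, m: int) -> float:
    """Smallest slope-adjusted band radius admitting a warping path."""
    slope = (m - 1) / (n - 1) if n > 1 else 0.0
    # Candidate radii are the distances of grid nodes to the band center.
    cand = np.unique(np.abs(np.arange(n)[:, None] * slope - np.arange(m)[None, :]))
    for r in cand:
        lo, hi = _band_bounds(n, m, float(r))
        if _band_feasible(lo, hi, m):
            return float(r)
    return float(max(n, m))  # unbanded is always feasible


@njit(cache=True)
def _dp(x, y, lo, hi):  # pragma: no cover - exercised via dtw()
    n = x.shape[0]
    m = y.shape[0]
    M = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(lo[i], hi[i] + 1):
            w = (x[i] - y[j]) ** 2
            if i == 0 and j == 0:
                M[0, 0] = w
            else:
                best = np.inf
                if i > 0 and j > 0 and M[i - 1, j - 1] < best:
                    best = M[i - 1, j - 1]
                if i > 0 and M[i - 1, j] < best:
                    best = M[i - 1, j]
                if j > 0 and M[i, j - 1] < best:
                    best = M[i, j - 1]
                if best < np.inf:
                    M[i, j] = w + best
    return M


@njit(cache=True)
def _backtrace(M):  # pragma: no cover - exercised via dtw()
    """One optimal path; ties broken diagonal > vertical > horizontal."""
    n, m = M.shape
    L = 0
    ii = np.empty(n + m - 1, dtype=np.int64)
    jj = np.empty(n + m - 1, dtype=np.int64)
    i, j = n - 1, m - 1
    ii[L] = i
    jj[L] = j
    while i > 0 or j > 0:
        best = np.inf
        if i > 0 and j > 0 and M[i - 1, j - 1] < best:
            best = M[i - 1, j - 1]
        if i > 0 and M[i - 1, j] < best:
            best = M[i - 1, j]
        if j > 0 and M[i, j - 1] < best:
            best = M[i, j - 1]
        if i > 0 and j > 0 and M[i - 1, j - 1] == best:
            i, j = i - 1, j - 1
        elif i > 0 and M[i - 1, j] == best:
            i = i - 1
        else:
            j = j - 1
        L += 1
        ii[L] = i
        jj[L] = j
    return ii[: L + 1][::-1].copy(), jj[: L + 1][::-1].copy()


def _as_seq(s) -> np.ndarray:
    a = np.asarray(s, dtype=np.float64)
    if a.ndim != 1 or a.shape[0] < 1:
        raise ValueError("DTW requires one-dimensional sequences of length >= 1")
    return a


def dtw(s1, s2, band_radius: float | None = None) -> DTWResult:
    """Optimal warping path and cost between two sequences.

    Parameters
    ----------
    s1, s2 : sequence of float
        The two profiles (length >= 1 each).
    band_radius : float or None
        Half-width of the slope-adjusted Sakoe-Chiba corridor, in bins.
        ``None`` (or any radius >= max(n, m)) disables banding and gives
        the unrestricted optimum.

    Returns
    -------
    DTWResult
        ``cost`` is the minimal summed squared difference along an
        admissible path, ``normalized`` the cost divided by the number
        of path nodes, ``path`` one optimal path (ties broken
        diagonal > vertical > horizontal during backtrace).

    Raises
    ------
    BandError
        If the band excludes every valid path; the error names the
        minimal feasible radius.
    """
    x, y = _as_seq(s1), _as_seq(s2)
    n, m = x.shape[0], y.shape[0]
    lo, hi = _band_bounds(n, m, band_radius)
    if band_radius is not None and not _band_feasible(lo, hi, m):
        raise BandError(n, m, band_radius, min_feasible_radius(n, m))
    M = _dp(x, y, lo, hi)
    if not np.isfinite(M[n - 1, m - 1]):
        raise BandError(n, m, band_radius, min_feasible_radius(n, m))
    ii, jj = _backtrace(M)
    path = WarpingPath(np.column_stack([ii, jj]))
    cost = float(M[n - 1, m - 1])
    return DTWResult(cost=cost, normalized=cost / len(path), path=path,
                     band_radius=band_radius)


@njit(cache=True)
def _cost_and_len(x, y, lo, hi):  # pragma: no cover - exercised via dtw_distance
    M = _dp(x, y, lo, hi)
    n, m = M.shape
    if not np.isfinite(M[n - 1, m - 1]):
        return np.inf, 0
    ii, jj = _backtrace(M)
    return M[n - 1, m - 1], ii.shape[0]


def dtw_distance(s1, s2, band_radius: float | None = None) -> float:
    """Path-length-normalized DTW cost (the distance used by the SOM)."""
    x, y = _as_seq(s1), _as_seq(s2)
    n, m = x.shape[0], y.shape[0]
    lo, hi = _band_bounds(n, m, band_radius)
    cost, length = _cost_and_len(x, y, lo, hi)
    if length == 0:
        raise BandError(n, m, band_radius, min_feasible_radius(n, m))
    return float(cost) / length


def pairwise_distances(sequences, band_radius: float | None = None) -> np.ndarray:
    """Symmetric matrix of normalized DTW distances between sequences."""
    k = len(sequences)
    D = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d = dtw_distance(sequences[a], sequences[b], band_radius)
            D[a, b] = D[b, a] = d
    return D


def write_distance_matrix(path, ids, D: np.ndarray) -> None:
    """Square distance matrix as TSV with an id header row and column."""
    ids = list(ids)
    if D.shape != (len(ids), len(ids)):
        raise ValueError("matrix shape does not match the id list")
    with open(path, "w") as fh:
        fh.write("\t".join([""] + ids) + "\n")
        for name, row in zip(ids, D):
            fh.write("\t".join([name] + [f"{v:.6g}" for v in row]) + "\n")
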