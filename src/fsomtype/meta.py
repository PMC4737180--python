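"""Cross-sample consolidation of per-sample FSOM clusterings.

Each sample's clusters are summarized by their per-bin median profile
(on the signed-offset bin grid, so truncated members contribute to the
bins they possess).  The medians of all samples are then merged by
complete-linkage hierarchical clustering under the unbanded normalized
DTW distance, the dendrogram is cut into a small number of super-groups
(default 4, labeled I..IV by increasing overall methylation), and event
memberships are compared across samples: a membership-sharing edge list
between (group, sample) nodes and a per-sample group ratio map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dtw import dtw_distance
from .profiles import Profile

__all__ = ["ClusterMedian", "SuperGrouping", "median_profiles",
           "meta_cluster", "membership_sharing", "roman", "to_newick"]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def roman(i: int) -> str:
    """1-based group index as a Roman numeral (I..X)."""
    return _ROMAN[i - 1]


@dataclass
class ClusterMedian:
    """Median methylation profile of one cluster of one sample."""

    sample: str
    row: int
    col: int
    values: np.ndarray
    offsets: list[tuple[str, int]]  # (side, signed border offset) per bin
    n_members: int

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.sample, self.row, self.col)


@dataclass
class SuperGrouping:
    """Dendrogram plus super-group labels for the cluster medians."""

    linkage: np.ndarray                      # scipy linkage matrix
    labels: list[str]                        # per median, "I".."IV"
    group_of: dict[tuple[str, int, int], str]
    n_groups: int
    distance: np.ndarray = field(repr=False, default=None)


def median_profiles(assignments: dict[str, tuple[int, int]],
                    profiles: list[Profile], sample: str,
                    min_members: int = 5) -> list[ClusterMedian]:
    """Per-bin median profile of every sufficiently large cluster.

    Bins are aligned by (side, signed offset from the border); each
    member contributes to the bins it possesses, so truncated members
    shorten nothing.  Clusters with fewer than ``min_members`` members
    are skipped.
    """
    by_cluster: dict[tuple[int, int], list[Profile]] = {}
    for p in profiles:
        rc = assignments.get(p.event_id)
        if rc is not None:
            by_cluster.setdefault(rc, []).append(p)
    out = []
    for rc in sorted(by_cluster):
        members = by_cluster[rc]
        if len(members) < min_members:
            continue
        per_bin: dict[tuple[str, int], list[float]] = {}
        for p in members:
            for key, v in zip(p.bin_offsets(), p.values):
                per_bin.setdefault(key, []).append(float(v))
        # IE block first, intron side (negative offsets) to exon side,
        # then the EI block exon -> intron: vector order of the profiles.
        keys = sorted(per_bin, key=lambda k: (k[0] == "EI", k[1]))
        vals = np.array([np.median(per_bin[k]) for k in keys])
        out.append(ClusterMedian(sample=sample, row=rc[0], col=rc[1],
                                 values=vals, offsets=keys,
                                 n_members=len(members)))
    return out


def meta_cluster(medians: list[ClusterMedian], n_groups: int = 4,
                 band_radius: float | None = None) -> SuperGrouping:
    """Complete-linkage grouping of cluster medians under DTW distance.

    The dendrogram is cut to exactly ``n_groups`` groups, which are
    labeled I.. by increasing mean methylation of their member medians
    (I = least methylated).
    """
    if len(medians) < n_groups:
        raise ValueError(
            f"need at least {n_groups} cluster medians, got {len(medians)}")
    k = len(medians)
    D = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d = dtw_distance(medians[a].values, medians[b].values, band_radius)
            D[a, b] = D[b, a] = d
    Z = linkage(squareform(D, checks=False), method="complete")
    raw = fcluster(Z, t=n_groups, criterion="maxclust")
    means = {g: np.mean([float(np.mean(m.values))
                         for m, gg in zip(medians, raw) if gg == g])
             for g in np.unique(raw)}
    order = sorted(means, key=means.get)
    rename = {g: roman(i + 1) for i, g in enumerate(order)}
    labels = [rename[g] for g in raw]
    group_of = {m.key: lab for m, lab in zip(medians, labels)}
    return SuperGrouping(linkage=Z, labels=labels, group_of=group_of,
                         n_groups=len(order), distance=D)


def membership_sharing(groupings: dict[str, dict[str, str]],
                       min_edge: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-sample membership-sharing edges and per-sample ratio map.

    ``groupings`` maps sample -> (event_id -> super-group label).  For
    every sample pair, the edge weight between group g1 at sample s1 and
    g2 at s2 is the fraction of the pair's commonly covered events that
    lie in g1 at s1 and g2 at s2; edges below ``min_edge`` are omitted.
    The ratio map gives, per sample, the fraction of its covered events
    in each super-group (rows sum to 1).
    """
    samples = sorted(groupings)
    if len(samples) < 2:
        raise ValueError("membership sharing needs at least 2 samples")
    edges = []
    for ai in range(len(samples)):
        for bi in range(ai + 1, len(samples)):
            s1, s2 = samples[ai], samples[bi]
            g1, g2 = groupings[s1], groupings[s2]
            common = sorted(set(g1) & set(g2))
            if not common:
                continue
            counts: dict[tuple[str, str], int] = {}
            for e in common:
                key = (g1[e], g2[e])
                counts[key] = counts.get(key, 0) + 1
            for (a, b), c in sorted(counts.items()):
                w = c / len(common)
                if w >= min_edge:
                    edges.append({"sample_a": s1, "group_a": a,
                                  "sample_b": s2, "group_b": b,
                                  "weight": w, "n_common": len(common)})
    edge_df = pd.DataFrame(edges, columns=["sample_a", "group_a", "sample_b",
                                           "group_b", "weight", "n_common"])
    all_groups = sorted({g for gg in groupings.values() for g in gg.values()})
    ratio_rows = []
    for s in samples:
        gg = groupings[s]
        n = len(gg)
        row = {"sample": s}
        for g in all_groups:
            row[g] = sum(1 for v in gg.values() if v == g) / n if n else 0.0
        ratio_rows.append(row)
    ratio_df = pd.DataFrame(ratio_rows, columns=["sample"] + all_groups)
    return edge_df, ratio_df


def to_newick(grouping: SuperGrouping, medians: list[ClusterMedian]) -> str:
    """Dendrogram as a Newick string; leaves named sample:row:col."""
    from scipy.cluster.hierarchy import to_tree

    names = [f"{m.sample}:{m.row}:{m.col}" for m in medians]
    root = to_tree(grouping.linkage)

    def rec(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = rec(node.left), rec(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return rec(root) + ";"
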