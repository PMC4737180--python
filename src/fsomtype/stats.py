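"""Association statistics linking methylation-profile clusters to
splicing properties.

Each biological property (Ψ inclusion score, host-gene FPKM, exon and
intron lengths, distance to TSS, GC/CpG ratios, ...) is tested per
cluster against the background — the *entire* AS event set of the
sample, cluster members included — with a two-sided Mann-Whitney U
test.  Because the background contains the cluster, the tests are
conservative for large clusters.

Border-resolved properties are tested per 20 bp bin (aligned by signed
offset from the border, not by warping, since truncation makes absolute
positions incomparable); a cluster is flagged only when more than 80%
of its testable bins agree on a significant direction.

Motif enrichment/depletion per cluster uses the hypergeometric
distribution over exact IUPAC consensus hits (either strand).  All
p-value families are Benjamini-Hochberg adjusted at FDR 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import MotifSet
from .profiles import Profile

__all__ = ["test_property", "binwise_border_test", "BorderTestResult",
           "motif_enrichment", "fdr_adjust", "iupac_to_regex",
           "reverse_complement", "scan_motifs", "property_report",
           "motif_report"]

#: largest product of group sizes for which the exact U distribution is used
EXACT_LIMIT = 400


def test_property(cluster_values, background_values):
    """Two-sided Mann-Whitney U test of a cluster against the background.

    Exact null distribution when the product of the group sizes is at
    most 400 and the pooled values are tie-free; the tie-corrected
    normal approximation otherwise.  Returns ``(U, p, direction)`` where
    direction is ``"high"``/``"low"`` by the sign of the median
    difference (``None`` when the medians are equal).  Fully tied data
    give p = 1 and no direction.
    """
    x = np.asarray(cluster_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.shape[0] < 3 or y.shape[0] < 3:
        raise ValueError("need at least 3 values on each side")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).shape[0] == 1:
        return float(x.shape[0] * y.shape[0] / 2.0), 1.0, None
    has_ties = np.unique(pooled).shape[0] < pooled.shape[0]
    method = "exact" if (x.shape[0] * y.shape[0] <= EXACT_LIMIT
                         and not has_ties) else "asymptotic"
    u, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
    med = float(np.median(x) - np.median(y))
    direction = "high" if med > 0 else ("low" if med < 0 else None)
    return float(u), float(min(p, 1.0)), direction


@dataclass
class BorderTestResult:
    """Outcome of the per-bin border test for one cluster."""

    flag: str | None        # "high" | "low" | None
    n_tested: int
    n_high: int             # significant-high bins after FDR
    n_low: int


def binwise_border_test(cluster_profiles: list[Profile],
                        background_profiles: list[Profile],
                        frac: float = 0.8, level: float = 0.05,
                        min_n: int = 5) -> BorderTestResult:
    """Test every 20 bp border bin and flag single-trend clusters.

    Bins are indexed by (side, signed offset from the border); only
    offsets carried by at least ``min_n`` events in both groups are
    tested.  Each bin gets a :func:`test_property` call; p-values are
    FDR-adjusted across the tested bins, and the cluster is flagged
    high (low) when strictly more than ``frac`` of the tested bins are
    significant with that direction.
    """
    def collect(profiles):
        per_bin: dict[tuple[str, int], list[float]] = {}
        for p in profiles:
            for (key, v) in zip(p.bin_offsets(), p.values):
                per_bin.setdefault(key, []).append(float(v))
        return per_bin

    cl = collect(cluster_profiles)
    bg = collect(background_profiles)
    keys = sorted(k for k in cl
                  if len(cl[k]) >= min_n and len(bg.get(k, [])) >= min_n)
    if not keys:
        return BorderTestResult(flag=None, n_tested=0, n_high=0, n_low=0)
    pvals, dirs = [], []
    for k in keys:
        _, p, d = test_property(cl[k], bg[k])
        pvals.append(p)
        dirs.append(d)
    _, flags = fdr_adjust(pvals, level)
    n_high = sum(1 for f, d in zip(flags, dirs) if f and d == "high")
    n_low = sum(1 for f, d in zip(flags, dirs) if f and d == "low")
    flag = None
    if n_high > frac * len(keys):
        flag = "high"
    elif n_low > frac * len(keys):
        flag = "low"
    return BorderTestResult(flag=flag, n_tested=len(keys),
                            n_high=n_high, n_low=n_low)


def motif_enrichment(cluster_hits: int, cluster_n: int,
                     bg_hits: int, bg_n: int) -> tuple[float, float]:
    """Hypergeometric enrichment and depletion tails for one cluster.

    With X ~ Hypergeom(N=bg_n, K=bg_hits, n=cluster_n):
    p_enrich = P[X >= cluster_hits], p_deplete = P[X <= cluster_hits].
    """
    if cluster_n > bg_n:
        raise ValueError("cluster larger than background")
    if not (0 <= cluster_hits <= cluster_n and 0 <= bg_hits <= bg_n):
        raise ValueError("hit counts exceed group sizes")
    p_enrich = float(hypergeom.sf(cluster_hits - 1, bg_n, bg_hits, cluster_n))
    p_deplete = float(hypergeom.cdf(cluster_hits, bg_n, bg_hits, cluster_n))
    return min(p_enrich, 1.0), min(p_deplete, 1.0)


def fdr_adjust(pvals, level: float = 0.05):
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return q, q <= level


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def iupac_to_regex(consensus: str) -> re.Pattern:
    """Compile an IUPAC consensus string into a nucleotide regex."""
    try:
        return re.compile("".join(_IUPAC[c] for c in consensus.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc} in {consensus!r}") from None


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_motifs(sequences: dict[str, str], motifs: MotifSet) -> pd.DataFrame:
    """Hit table: does each sequence contain each motif on either strand?

    Index = sequence id, columns = motif names, values boolean.  A hit
    is at least one exact IUPAC-consensus match in the sequence or its
    reverse complement.
    """
    out = {}
    for name, consensus in motifs:
        rx = iupac_to_regex(consensus)
        out[name] = [bool(rx.search(seq.upper()))
                     or bool(rx.search(reverse_complement(seq)))
                     for seq in sequences.values()]
    return pd.DataFrame(out, index=list(sequences.keys()))


def _cluster_label(rc: tuple[int, int]) -> str:
    return f"Clu({rc[0]},{rc[1]})"


def property_report(assignments: dict[str, tuple[int, int]],
                    properties: pd.DataFrame,
                    level: float = 0.05) -> pd.DataFrame:
    """Per (cluster, property) U-test report against the full event set.

    ``properties`` is indexed by event_id with one numeric column per
    property; NaNs are skipped per property.  FDR is applied per
    property across clusters (the smallest defensible family).  The
    returned direction is only reported for significant rows.
    """
    clusters = sorted(set(assignments.values()))
    rows = []
    for prop in properties.columns:
        series = properties[prop].dropna()
        bg = series.to_numpy(dtype=float)
        sub = []
        for rc in clusters:
            members = [e for e, a in assignments.items()
                       if a == rc and e in series.index]
            if len(members) < 3 or bg.shape[0] < 3:
                sub.append((rc, np.nan, np.nan, None))
                continue
            u, p, d = test_property(series.loc[members].to_numpy(dtype=float), bg)
            sub.append((rc, u, p, d))
        pvals = [p for (_, _, p, _) in sub if not np.isnan(p)]
        qmap = {}
        if pvals:
            q, flags = fdr_adjust(pvals, level)
            it = iter(zip(q, flags))
            for rc, u, p, d in sub:
                if not np.isnan(p):
                    qmap[rc] = next(it)
        for rc, u, p, d in sub:
            qq, sig = qmap.get(rc, (np.nan, False))
            rows.append({
                "cluster": _cluster_label(rc), "property": prop,
                "n": sum(1 for e, a in assignments.items() if a == rc),
                "U": u, "p": p, "q": qq,
                "significant": bool(sig),
                "direction": d if sig else "",
            })
    return pd.DataFrame(rows, columns=["cluster", "property", "n", "U", "p",
                                       "q", "significant", "direction"])


def motif_report(assignments: dict[str, tuple[int, int]],
                 hits: dict[str, pd.DataFrame],
                 level: float = 0.05) -> pd.DataFrame:
    """Per (cluster, motif, border side) hypergeometric report.

    ``hits`` maps border side ("IE"/"EI") to a boolean event x motif hit
    table from :func:`scan_motifs`.  FDR is applied per motif and side
    across clusters, separately for the enrichment and depletion tails;
    the flags are mutually exclusive.
    """
    clusters = sorted(set(assignments.values()))
    rows = []
    for side, table in hits.items():
        covered = [e for e in table.index if e in assignments]
        for motif in table.columns:
            bg_hits = int(table.loc[covered, motif].sum())
            bg_n = len(covered)
            sub = []
            for rc in clusters:
                members = [e for e in covered if assignments[e] == rc]
                ch = int(table.loc[members, motif].sum())
                pe, pd_ = motif_enrichment(ch, len(members), bg_hits, bg_n)
                sub.append((rc, ch, len(members), pe, pd_))
            qe, fe = fdr_adjust([s[3] for s in sub], level)
            qd, fd = fdr_adjust([s[4] for s in sub], level)
            for (rc, ch, cn, pe, pd_), qei, fei, qdi, fdi in zip(
                    sub, qe, fe, qd, fd):
                enr = bool(fei) and not bool(fdi)
                dep = bool(fdi) and not bool(fei)
                rows.append({
                    "cluster": _cluster_label(rc), "motif": motif,
                    "side": side, "cluster_hits": ch, "cluster_n": cn,
                    "bg_hits": bg_hits, "bg_n": bg_n,
                    "p_enrich": pe, "p_deplete": pd_,
                    "q_enrich": qei, "q_deplete": qdi,
                    "enriched": enr, "depleted": dep,
                })
    return pd.DataFrame(rows, columns=[
        "cluster", "motif", "side", "cluster_hits", "cluster_n",
        "bg_hits", "bg_n", "p_enrich", "p_deplete", "q_enrich",
        "q_deplete", "enriched", "depleted"])
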