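"""Readers and writers for every external format the tool touches.

Coordinate convention: 0-based, half-open (BED style) everywhere.

Formats
-------
* methylation track: 4-column whitespace-delimited bedGraph
  (``chrom  start  end  level``) with levels in [0, 1];
* AS events: TSV with a header naming the :class:`ASEvent` fields;
* motifs: two-column TSV of (name, IUPAC consensus);
* assignments / reports: TSV with a header and stable column order.

All writers are deterministic (fixed float formatting and column
order); leading ``#`` lines in any of the TSV dialects are treated as
comments (run-provenance stamps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationTrack", "ASEvent", "MotifSet", "TrackFormatError",
    "EventSchemaError", "read_track", "write_track", "read_events",
    "read_motifs", "write_assignments", "read_assignments", "write_report",
    "IUPAC_CODES",
]

#: Missing-bin sentinel: bins without CpG coverage are NaN, never 0 —
#: zero methylation is a valid measurement distinct from missing.
MISSING = np.nan

IUPAC_CODES = set("ACGTURYSWKMBDHVN")


class TrackFormatError(ValueError):
    """Malformed bedGraph line or out-of-range methylation level."""


class EventSchemaError(ValueError):
    """Event table lacks a mandatory column."""


@dataclass
class MethylationTrack:
    """Genome-wide methylation levels binned at a fixed resolution.

    ``levels[chrom]`` is a float array tiling the chromosome contiguously
    from coordinate 0; NaN marks bins without coverage.
    """

    resolution: int
    levels: dict[str, np.ndarray] = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return self.levels[chrom].shape[0]

    def region_values(self, chrom: str, start: int, end: int,
                      bin_size: int | None = None) -> np.ndarray:
        """Mean level per ``bin_size`` window of [start, end).

        Windows are anchored at ``start``; each window's value is the
        coverage-weighted mean of the overlapping track bins, ignoring
        missing portions (all-missing window -> NaN).  ``end - start``
        must be a multiple of ``bin_size`` (default: track resolution).
        """
        bs = bin_size or self.resolution
        if (end - start) % bs:
            raise ValueError("region length must be a multiple of bin_size")
        arr = self.levels.get(chrom)
        if arr is None:
            return np.full((end - start) // bs, MISSING)
        out = np.empty((end - start) // bs)
        for k in range(out.shape[0]):
            a, b = start + k * bs, start + (k + 1) * bs
            lo, hi = a // self.resolution, -(-b // self.resolution)
            wsum = vsum = 0.0
            for t in range(max(lo, 0), min(hi, arr.shape[0])):
                v = arr[t]
                if math.isnan(v):
                    continue
                # overlap as a fraction of the track bin keeps full-bin
                # reads bit-exact (weight 1.0, no rescaling round-off)
                ov = (min(b, (t + 1) * self.resolution)
                      - max(a, t * self.resolution)) / self.resolution
                wsum += ov
                vsum += ov * v
            out[k] = vsum / wsum if wsum > 0 else MISSING
        return out


@dataclass
class ASEvent:
    """One alternative-splicing event (skipped exon or retained intron).

    ``body_start``/``body_end`` delimit the skipped exon (SE) or retained
    intron (RI); ``upstream_limit``/``downstream_limit`` are the nearest
    neighboring exon/intron borders that bound the +/-200 bp expansion.
    """

    event_id: str
    event_type: str  # SE | RI
    chrom: str
    strand: str  # + | -
    body_start: int
    body_end: int
    upstream_limit: int
    downstream_limit: int
    psi: float | None = None
    fpkm: float | None = None
    tss_distance: float | None = None
    properties: dict[str, float] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return the list of violated invariants (empty if valid)."""
        problems = []
        if self.event_type not in ("SE", "RI"):
            problems.append(f"event_type {self.event_type!r} not SE/RI")
        if self.strand not in ("+", "-"):
            problems.append(f"strand {self.strand!r} not +/-")
        if not self.body_start < self.body_end:
            problems.append("body_start >= body_end")
        if not self.upstream_limit <= self.body_start:
            problems.append("upstream_limit > body_start")
        if not self.body_end <= self.downstream_limit:
            problems.append("body_end > downstream_limit")
        if self.psi is not None and not 0.0 <= self.psi <= 1.0:
            problems.append("psi out of range")
        return problems


@dataclass
class MotifSet:
    """Named splicing motifs as IUPAC consensus strings."""

    motifs: list[tuple[str, str]]

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)


def read_track(path, resolution: int = 20) -> MethylationTrack:
    """Read a bedGraph-dialect file into fixed-resolution bins.

    Interval values are averaged into bins weighted by overlap length;
    the denominator is restricted to the covered portion of a bin, so a
    partially covered bin carries the mean over its covered part only.
    Uncovered bins are missing (NaN).
    """
    sums: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise TrackFormatError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise TrackFormatError(f"{path}:{lineno}: {exc}") from None
            if start < 0 or end <= start:
                raise TrackFormatError(
                    f"{path}:{lineno}: bad interval [{start}, {end})")
            if not 0.0 <= value <= 1.0:
                raise TrackFormatError(
                    f"{path}:{lineno}: level {value} outside [0, 1]")
            per = sums.setdefault(chrom, {"w": {}, "v": {}})
            lo, hi = start // resolution, -(-end // resolution)
            for b in range(lo, hi):
                ov = (min(end, (b + 1) * resolution)
                      - max(start, b * resolution)) / resolution
                per["w"][b] = per["w"].get(b, 0.0) + ov
                per["v"][b] = per["v"].get(b, 0.0) + ov * value
    track = MethylationTrack(resolution=resolution)
    for chrom, per in sums.items():
        n = max(per["w"]) + 1
        arr = np.full(n, MISSING)
        for b, w in per["w"].items():
            arr[b] = per["v"][b] / w
        track.levels[chrom] = arr
    return track


def write_track(path, track: MethylationTrack) -> None:
    """Write non-missing bins back out as bedGraph (deterministic order)."""
    res = track.resolution
    with open(path, "w") as fh:
        for chrom in sorted(track.levels):
            arr = track.levels[chrom]
            for b in np.flatnonzero(~np.isnan(arr)):
                fh.write(f"{chrom}\t{b * res}\t{(b + 1) * res}\t{arr[b]:.6g}\n")


_MANDATORY = ["event_id", "event_type", "chrom", "strand",
              "body_start", "body_end", "upstream_limit", "downstream_limit"]
_OPTIONAL = ["psi", "fpkm", "tss_distance"]


def read_events(path) -> tuple[list[ASEvent], pd.DataFrame]:
    """Read and validate an AS-event table.

    Returns the valid events plus a rejection report (one row per
    rejected input row with the reasons joined by '; ').
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise EventSchemaError(f"{path}: missing mandatory columns {missing}")
    extra = [c for c in df.columns if c not in _MANDATORY + _OPTIONAL]
    events, rejects = [], []
    for _, row in df.iterrows():
        def opt(col):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        try:
            ev = ASEvent(
                event_id=str(row["event_id"]),
                event_type=str(row["event_type"]),
                chrom=str(row["chrom"]),
                strand=str(row["strand"]),
                body_start=int(row["body_start"]),
                body_end=int(row["body_end"]),
                upstream_limit=int(row["upstream_limit"]),
                downstream_limit=int(row["downstream_limit"]),
                psi=opt("psi"),
                fpkm=opt("fpkm"),
                tss_distance=opt("tss_distance"),
                properties={c: float(row[c]) for c in extra
                            if not pd.isna(row[c])},
            )
        except (TypeError, ValueError) as exc:
            rejects.append({"event_id": str(row.get("event_id", "?")),
                            "reason": f"unparseable row: {exc}"})
            continue
        problems = ev.validate()
        if problems:
            rejects.append({"event_id": ev.event_id,
                            "reason": "; ".join(problems)})
        else:
            events.append(ev)
    report = pd.DataFrame(rejects, columns=["event_id", "reason"])
    return events, report


def read_motifs(path) -> MotifSet:
    """Read a two-column TSV of (motif name, IUPAC consensus)."""
    motifs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, consensus = parts[0], parts[1].upper()
            bad = set(consensus) - IUPAC_CODES
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: non-IUPAC characters {sorted(bad)} "
                    f"in consensus {consensus!r}")
            motifs.append((name, consensus))
    return MotifSet(motifs)


def write_assignments(path, assignments: dict[str, tuple[int, int]],
                      stamp: str | None = None) -> None:
    """Write event -> (row, col) cluster assignments as TSV."""
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        fh.write("event_id\trow\tcol\n")
        for event_id in sorted(assignments):
            r, c = assignments[event_id]
            fh.write(f"{event_id}\t{r}\t{c}\n")


def read_assignments(path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"event_id": str, "row": int, "col": int})
    return {row.event_id: (row.row, row.col) for row in df.itertuples()}


def write_report(path, report: pd.DataFrame, stamp: str | None = None) -> None:
    """Write a report table deterministically (%.6g floats, fixed columns)."""
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        report.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                      lineterminator="\n")
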