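"""Build border-region methylation profiles for AS events.

For every event the +/-200 bp neighborhoods of its two borders are
extracted, binned at 20 bp, concatenated I/E-block-first in transcript
orientation, and returned as one variable-length vector.  When a 200 bp
expansion would cross the neighboring exon/intron border the expansion
stops early (whole bins only), so profiles from different events may
have different lengths — that is what the warping distance absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ASEvent, MethylationTrack

__all__ = ["Profile", "BorderRegion", "ProfileError", "extract_border_region",
           "build_profile", "build_profiles", "quantile_normalize",
           "write_profiles", "read_profiles"]


class ProfileError(ValueError):
    """Event unusable for profile construction (reason in message)."""


@dataclass(frozen=True)
class BorderRegion:
    """Genomic interval around one border, in genome coordinates."""

    chrom: str
    start: int
    end: int
    border: int        # the exon/intron boundary inside [start, end)
    intron_bins: int   # bins on the intron side of the border
    exon_bins: int     # bins on the exon side


@dataclass
class Profile:
    """Combined border-region methylation profile of one AS event.

    ``values`` runs 5'->3' in transcript orientation: first the I/E
    (acceptor) border block, then the E/I (donor) border block;
    ``border_index`` is the position where the E/I block begins.
    ``ie_intron_bins`` counts the bins of the I/E block lying on the
    intron side of the border, ``ei_exon_bins`` the bins of the E/I
    block on the exon side — together with the block lengths they place
    every bin at a signed offset from its border (offset 0 = first bin
    after the border in transcript orientation).
    """

    event_id: str
    values: np.ndarray
    border_index: int
    bin_size: int
    ie_intron_bins: int
    ei_exon_bins: int

    def __len__(self) -> int:
        return self.values.shape[0]

    def bin_offsets(self) -> list[tuple[str, int]]:
        """(side, signed offset from that side's border) per vector bin."""
        n = len(self.values)
        out = []
        for k in range(self.border_index):
            out.append(("IE", k - self.ie_intron_bins))
        for k in range(self.border_index, n):
            out.append(("EI", k - self.border_index - self.ei_exon_bins))
        return out


def _truncate(avail: int, flank_bp: int, bin_size: int) -> int:
    """Usable whole bins on one side of a border."""
    return min(avail, flank_bp) // bin_size


def extract_border_region(event: ASEvent, side: str, flank_bp: int = 200,
                          bin_size: int = 20) -> BorderRegion:
    """Genomic interval of up to ``flank_bp`` on each side of one border.

    ``side`` is in transcript orientation: ``"IE"`` is the acceptor
    (intron -> exon) border, ``"EI"`` the donor.  The intron-side
    extension is truncated at the neighboring exon/intron limit and the
    exon side at the opposite body border; truncation drops partial bins
    (floored to a bin boundary relative to the border).
    """
    if side not in ("IE", "EI"):
        raise ValueError(f"side must be IE or EI, not {side!r}")
    if flank_bp % bin_size:
        raise ValueError("flank_bp must be a multiple of bin_size")
    body_len = event.body_end - event.body_start
    at_start = (side == "IE") == (event.strand == "+")
    if at_start:  # border at body_start; intron extends genomically left
        border = event.body_start
        intron = _truncate(border - event.upstream_limit, flank_bp, bin_size)
        exon = _truncate(body_len, flank_bp, bin_size)
        start = border - intron * bin_size
        end = border + exon * bin_size
    else:         # border at body_end; intron extends genomically right
        border = event.body_end
        intron = _truncate(event.downstream_limit - border, flank_bp, bin_size)
        exon = _truncate(body_len, flank_bp, bin_size)
        start = border - exon * bin_size
        end = border + intron * bin_size
    if intron == 0 or exon == 0:
        raise ProfileError(
            f"{event.event_id}: {side} border region collapses to zero bins "
            f"on the {'intron' if intron == 0 else 'exon'} side")
    return BorderRegion(event.chrom, start, end, border, intron, exon)


def _impute(values: np.ndarray, max_gap: int, event_id: str) -> np.ndarray:
    """Linearly interpolate missing runs of length <= max_gap."""
    isna = np.isnan(values)
    if not isna.any():
        return values
    if isna.all():
        raise ProfileError(f"{event_id}: all bins missing")
    # length of each missing run
    run = 0
    for flag in isna:
        run = run + 1 if flag else 0
        if run > max_gap:
            raise ProfileError(
                f"{event_id}: missing run longer than {max_gap} bins")
    idx = np.arange(values.shape[0])
    out = values.copy()
    out[isna] = np.interp(idx[isna], idx[~isna], values[~isna])
    return out


def build_profile(track: MethylationTrack, event: ASEvent,
                  flank_bp: int = 200, bin_size: int = 20,
                  max_gap: int = 2) -> Profile:
    """Read both border regions from the track and assemble the profile.

    Minus-strand profiles are reversed so the vector always runs 5'->3'
    in transcript orientation with the I/E block first.  Isolated
    missing bins (runs of at most ``max_gap``) are linearly interpolated
    from flanking non-missing bins; longer runs make the event unusable
    (:class:`ProfileError`).
    """
    ie = extract_border_region(event, "IE", flank_bp, bin_size)
    ei = extract_border_region(event, "EI", flank_bp, bin_size)
    v_ie = track.region_values(event.chrom, ie.start, ie.end, bin_size)
    v_ei = track.region_values(event.chrom, ei.start, ei.end, bin_size)
    if event.strand == "-":
        v_ie = v_ie[::-1]
        v_ei = v_ei[::-1]
    values = np.concatenate([v_ie, v_ei])
    values = _impute(values, max_gap, event.event_id)
    return Profile(event_id=event.event_id, values=values,
                   border_index=v_ie.shape[0], bin_size=bin_size,
                   ie_intron_bins=ie.intron_bins, ei_exon_bins=ei.exon_bins)


def build_profiles(track: MethylationTrack, events: list[ASEvent],
                   flank_bp: int = 200, bin_size: int = 20,
                   max_gap: int = 2) -> tuple[list[Profile], pd.DataFrame]:
    """Batch profile construction; unusable events go into a report."""
    profiles, dropped = [], []
    for ev in events:
        try:
            profiles.append(build_profile(track, ev, flank_bp, bin_size, max_gap))
        except ProfileError as exc:
            dropped.append({"event_id": ev.event_id, "reason": str(exc)})
    return profiles, pd.DataFrame(dropped, columns=["event_id", "reason"])


def quantile_normalize(tracks: list[MethylationTrack]) -> list[MethylationTrack]:
    """Quantile-normalize methylation levels across samples genome-wide.

    Each sample's sorted non-missing bin values are replaced by the
    across-sample mean of order statistics (with interpolation when
    samples have different numbers of covered bins); tied values share
    the mean of the reference values they span.  Missing bins stay
    missing; within-sample rank order is preserved.
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs at least 2 tracks")
    res = tracks[0].resolution
    chroms = set(tracks[0].levels)
    for t in tracks[1:]:
        if t.resolution != res or set(t.levels) != chroms or any(
                t.n_bins(c) != tracks[0].n_bins(c) for c in chroms):
            raise ValueError("tracks have mismatched bin grids")
    order = sorted(chroms)
    flats = [np.concatenate([t.levels[c] for c in order]) for t in tracks]
    masks = [~np.isnan(f) for f in flats]
    values = [f[m] for f, m in zip(flats, masks)]
    sortvals = [np.sort(v) for v in values]
    counts = [v.shape[0] for v in values]
    if min(counts) == 0:
        raise ValueError("a track has no covered bins")

    def reference(n: int) -> np.ndarray:
        # mean of the samples' empirical quantile functions at n points
        u = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
        acc = np.zeros(n)
        for sv in sortvals:
            grid = np.linspace(0.0, 1.0, sv.shape[0]) if sv.shape[0] > 1 \
                else np.array([0.5])
            acc += np.interp(u, grid, sv)
        return acc / len(sortvals)

    out = []
    for t, flat, mask, v in zip(tracks, flats, masks, values):
        ref = reference(v.shape[0])
        ranks = np.argsort(v, kind="stable")
        q = np.empty_like(v)
        q[ranks] = ref
        # ties share the mean of their spanned reference values
        uniq, inv = np.unique(v, return_inverse=True)
        if uniq.shape[0] < v.shape[0]:
            sums = np.bincount(inv, weights=q)
            cnts = np.bincount(inv)
            q = (sums / cnts)[inv]
        new_flat = np.full_like(flat, np.nan)
        new_flat[mask] = q
        nt = MethylationTrack(resolution=res)
        pos = 0
        for c in order:
            n = t.n_bins(c)
            nt.levels[c] = new_flat[pos:pos + n].copy()
            pos += n
        out.append(nt)
    return out


def write_profiles(path, profiles: list[Profile], stamp: str | None = None) -> None:
    """Profiles as TSV: id, geometry columns, comma-joined values."""
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        fh.write("event_id\tborder_index\tie_intron_bins\tei_exon_bins"
                 "\tbin_size\tvalues\n")
        for p in profiles:
            vals = ",".join(f"{v:.6g}" for v in p.values)
            fh.write(f"{p.event_id}\t{p.border_index}\t{p.ie_intron_bins}"
                     f"\t{p.ei_exon_bins}\t{p.bin_size}\t{vals}\n")


def read_profiles(path) -> list[Profile]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"event_id": str})
    out = []
    for row in df.itertuples():
        values = np.array([float(x) for x in row.values.split(",")])
        out.append(Profile(event_id=row.event_id, values=values,
                           border_index=int(row.border_index),
                           bin_size=int(row.bin_size),
                           ie_intron_bins=int(row.ie_intron_bins),
                           ei_exon_bins=int(row.ei_exon_bins)))
    return out
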