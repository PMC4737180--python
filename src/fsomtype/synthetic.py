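"""Seeded generators of methylation tracks, AS-event tables and profiles.

Every stage of the pipeline is testable without downloads: labeled
profile mixtures exercise the DTW/SOM/consensus machinery directly, and
a track + event-table + FASTA generator exercises the I/O and
association layers end to end.  Shapes emulate the kinds of border
patterns the typing recovers from real bisulfite data (uniformly high
or low methylation, steps across the border, dips at the border,
ramps); Ψ is generated with a positive linear coupling to the mean
methylation so the association tests have signal to find, and motifs
are planted at shape-dependent rates for the enrichment tests.

All generators are pure functions of (specification, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .io import ASEvent
from .profiles import Profile

__all__ = ["ShapeSpec", "SHAPE_LIBRARY", "default_shapes", "make_profiles",
           "make_track_and_events", "SyntheticDataset"]

# Prototype functions over u in [0, 1] (the combined border vector:
# I/E border near u = 0.25, E/I border near u = 0.75).


def _flat(level: float) -> Callable[[np.ndarray], np.ndarray]:
    return lambda u: np.full_like(u, level)


def _step_up(u):
    return np.where(u < 0.5, 0.2, 0.8)


def _step_down(u):
    return np.where(u < 0.5, 0.8, 0.2)


def _dip(u):
    borders = np.exp(-((u - 0.25) ** 2) / (2 * 0.06 ** 2)) + \
        np.exp(-((u - 0.75) ** 2) / (2 * 0.06 ** 2))
    return np.clip(0.8 - 0.6 * borders, 0.0, 1.0)


def _ramp(u):
    return 0.1 + 0.8 * u


SHAPE_LIBRARY: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "flat-low": _flat(0.2),
    "flat-high": _flat(0.8),
    "step-up-at-border": _step_up,
    "step-down": _step_down,
    "dip-at-border": _dip,
    "ramp": _ramp,
}


@dataclass
class ShapeSpec:
    """One profile family: prototype shape plus noise/geometry settings.

    ``length_jitter`` varies each border block's length by up to that
    many bins; ``trunc_prob``/``trunc_range`` optionally shorten the
    intron side of a block, emulating events whose 200 bp expansion was
    stopped early by a neighboring border.
    """

    name: str
    prototype: Callable[[np.ndarray], np.ndarray]
    noise_sd: float = 0.1
    length_jitter: int = 0
    trunc_prob: float = 0.0
    trunc_range: tuple[int, int] = (1, 3)
    planted_motif: str | None = None
    motif_rate: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def default_shapes(names=("flat-low", "flat-high", "step-up-at-border",
                          "dip-at-border"), **kw) -> list[ShapeSpec]:
    """The standard four-family mixture used across the test suite."""
    return [ShapeSpec(name=n, prototype=SHAPE_LIBRARY[n], **kw) for n in names]


def _geometry(shape: ShapeSpec, rng: np.random.Generator, flank_bins: int,
              intron_only: bool) -> tuple[int, int, int, int]:
    """Draw (ie_intron, ie_exon, ei_exon, ei_intron) block geometry.

    With ``intron_only`` the jitter/truncation may only shorten the
    intron sides below ``flank_bins`` — the variation an event table can
    encode through its upstream/downstream limits.  Otherwise blocks may
    also lengthen, which free-standing profile mixtures allow.
    """
    j = shape.length_jitter
    lohi = (-j, 1) if intron_only else (-j, j + 1)
    ie_i = flank_bins + (int(rng.integers(*lohi)) if j else 0)
    ei_i = flank_bins + (int(rng.integers(*lohi)) if j else 0)
    ie_e = flank_bins + (0 if intron_only or not j
                         else int(rng.integers(-j, j + 1)))
    ei_e = flank_bins + (0 if intron_only or not j
                         else int(rng.integers(-j, j + 1)))
    if shape.trunc_prob > 0 and rng.random() < shape.trunc_prob:
        k = int(rng.integers(shape.trunc_range[0], shape.trunc_range[1] + 1))
        if rng.random() < 0.5:
            ie_i = max(ie_i - k, 2)
        else:
            ei_i = max(ei_i - k, 2)
    return max(ie_i, 2), max(ie_e, 2), max(ei_e, 2), max(ei_i, 2)


def _sample_profile(shape: ShapeSpec, rng: np.random.Generator,
                    event_id: str, geometry: tuple[int, int, int, int]
                    ) -> Profile:
    """Prototype sampled at the geometry's length plus clipped noise.

    The prototype is evaluated on the untruncated grid and the missing
    intron-side bins dropped, as real truncation removes genomic bins
    rather than rescaling the shape.
    """
    ie_i, ie_e, ei_e, ei_i = geometry
    full_i = max(ie_i, ei_i)
    total_full = full_i + ie_e + ei_e + full_i
    u = (np.arange(total_full) + 0.5) / total_full
    base = shape.prototype(u)
    if shape.noise_sd > 0:
        base = base + rng.normal(0.0, shape.noise_sd, size=total_full)
    values = np.clip(base, 0.0, 1.0)
    values = values[full_i - ie_i: total_full - (full_i - ei_i)]
    return Profile(event_id=event_id, values=values,
                   border_index=ie_i + ie_e, bin_size=20,
                   ie_intron_bins=ie_i, ei_exon_bins=ei_e)


def make_profiles(shapes: list[ShapeSpec], n_per_shape: int, seed: int = 0,
                  flank_bins: int = 10) -> tuple[list[Profile], np.ndarray]:
    """Labeled profile mixture: n_per_shape draws from each shape family."""
    if not shapes or n_per_shape < 1:
        raise ValueError("need at least one shape and one profile per shape")
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for si, shape in enumerate(shapes):
        for k in range(n_per_shape):
            geom = _geometry(shape, rng, flank_bins, intron_only=False)
            profiles.append(_sample_profile(
                shape, rng, f"ev_{shape.name}_{k:04d}", geom))
            labels.append(si)
    return profiles, np.array(labels)


@dataclass
class SyntheticDataset:
    """File-backed synthetic sample plus its generation truth."""

    track_path: Path
    events_path: Path
    fasta_path: Path
    truth_path: Path
    events: list[ASEvent]
    profiles: list[Profile]
    labels: np.ndarray
    shape_names: list[str]


_BASES = np.array(list("ACGT"))


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_track_and_events(shapes: list[ShapeSpec], n_events: int,
                          genome_size: int = 2_000_000, seed: int = 0,
                          out_dir: str | Path = ".", chrom: str = "chrSim",
                          flank_bp: int = 200, bin_size: int = 20,
                          psi_coupling: float = 0.7, psi_noise: float = 0.1
                          ) -> SyntheticDataset:
    """Write a consistent bedGraph track, event table, FASTA and truth.

    Events are placed on a regular stride without border-region overlap,
    alternating strands; the binned track values around each event's
    borders realize that event's shape, so building profiles from the
    written files recovers the generated profiles bit-exactly.  Length
    variation is carried by the upstream/downstream limits (intron-side
    truncation), which is what an event table can encode.  Ψ is mean
    methylation scaled by ``psi_coupling`` plus Gaussian noise (clipped
    to [0, 1]); border sequences are random with shape-dependent motif
    planting.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stride = genome_size // n_events
    flank_bins = flank_bp // bin_size
    body_len = 2 * flank_bp  # full exon-side flanks on both borders
    need = body_len + 4 * flank_bp
    if stride < need:
        raise ValueError(
            f"genome of {genome_size} bp too small for {n_events} events "
            f"(need >= {need} bp per event)")
    rng = np.random.default_rng(seed)
    events, profiles, labels = [], [], []
    seqs: dict[str, str] = {}
    for i in range(n_events):
        lab = i % len(shapes)
        shape = shapes[lab]
        strand = "+" if (i // len(shapes)) % 2 == 0 else "-"
        event_id = f"ev{i:05d}"
        geom = _geometry(shape, rng, flank_bins, intron_only=True)
        p = _sample_profile(shape, rng, event_id, geom)
        body_start = i * stride + 2 * flank_bp
        body_end = body_start + body_len
        ei_intron = (len(p) - p.border_index) - p.ei_exon_bins
        if strand == "+":
            upstream_limit = body_start - p.ie_intron_bins * bin_size
            downstream_limit = body_end + ei_intron * bin_size
        else:
            upstream_limit = body_start - ei_intron * bin_size
            downstream_limit = body_end + p.ie_intron_bins * bin_size
        ev = ASEvent(event_id=event_id, event_type="SE", chrom=chrom,
                     strand=strand, body_start=body_start, body_end=body_end,
                     upstream_limit=upstream_limit,
                     downstream_limit=downstream_limit)
        ev.psi = float(np.clip(
            psi_coupling * float(np.mean(p.values))
            + rng.normal(0.15, psi_noise), 0.0, 1.0))
        ev.fpkm = float(rng.lognormal(2.0, 1.0))
        ev.tss_distance = float(rng.integers(500, 100_000))
        events.append(ev)
        profiles.append(p)
        labels.append(lab)
        for side in ("IE", "EI"):
            seq = _random_seq(rng, 2 * flank_bp)
            if shape.planted_motif and rng.random() < shape.motif_rate:
                pos = int(rng.integers(0, len(seq) - len(shape.planted_motif)))
                seq = (seq[:pos] + shape.planted_motif
                       + seq[pos + len(shape.planted_motif):])
            seqs[f"{event_id}::{side}"] = seq

    track_path = out_dir / "track.bedgraph"
    with open(track_path, "w") as fh:
        for ev, p in zip(events, profiles):
            for gstart, v in sorted(_genomic_bins(ev, p, bin_size)):
                fh.write(f"{chrom}\t{gstart}\t{gstart + bin_size}\t{v:.17g}\n")

    events_path = out_dir / "events.tsv"
    with open(events_path, "w") as fh:
        fh.write("event_id\tevent_type\tchrom\tstrand\tbody_start\tbody_end"
                 "\tupstream_limit\tdownstream_limit\tpsi\tfpkm"
                 "\ttss_distance\n")
        for ev in events:
            fh.write(f"{ev.event_id}\t{ev.event_type}\t{ev.chrom}\t{ev.strand}"
                     f"\t{ev.body_start}\t{ev.body_end}\t{ev.upstream_limit}"
                     f"\t{ev.downstream_limit}\t{ev.psi:.6g}\t{ev.fpkm:.6g}"
                     f"\t{ev.tss_distance:.6g}\n")

    fasta_path = out_dir / "borders.fa"
    with open(fasta_path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")

    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("event_id\tshape\tlabel\n")
        for ev, lab in zip(events, labels):
            fh.write(f"{ev.event_id}\t{shapes[lab].name}\t{lab}\n")

    return SyntheticDataset(track_path=track_path, events_path=events_path,
                            fasta_path=fasta_path, truth_path=truth_path,
                            events=events, profiles=profiles,
                            labels=np.array(labels),
                            shape_names=[s.name for s in shapes])


def _genomic_bins(ev: ASEvent, p: Profile, bin_size: int):
    """Map profile bins to (genomic bin start, value) pairs.

    Inverse of profile construction: the I/E block covers the
    transcript-upstream border, the E/I block the downstream one;
    minus-strand profiles are laid out reversed.
    """
    ie_vals = p.values[:p.border_index]
    ei_vals = p.values[p.border_index:]
    out = []
    if ev.strand == "+":
        ie_start = ev.body_start - p.ie_intron_bins * bin_size
        for k, v in enumerate(ie_vals):
            out.append((ie_start + k * bin_size, float(v)))
        ei_start = ev.body_end - p.ei_exon_bins * bin_size
        for k, v in enumerate(ei_vals):
            out.append((ei_start + k * bin_size, float(v)))
    else:
        # I/E border is at body_end; the block runs genomically right->left
        ie_end = ev.body_end + p.ie_intron_bins * bin_size
        for k, v in enumerate(ie_vals):
            out.append((ie_end - (k + 1) * bin_size, float(v)))
        ei_end = ev.body_start + p.ei_exon_bins * bin_size
        for k, v in enumerate(ei_vals):
            out.append((ei_end - (k + 1) * bin_size, float(v)))
    return out
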