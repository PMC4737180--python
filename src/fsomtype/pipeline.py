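"""End-to-end orchestration: profiles -> k selection -> typing -> stats
-> cross-sample meta-grouping, with seeded reproducibility.

One global seed deterministically derives per-stage seeds; every
artifact is a TSV stamped with the configuration hash and seed on a
leading comment line.  The CLI in :mod:`fsomtype.cli` is a thin wrapper
over these functions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, meta, selection, som, stats
from .config import RunConfig
from .profiles import build_profiles, read_profiles, write_profiles

__all__ = ["stage_seed", "run_profiles", "run_select_k", "run_typing",
           "run_association", "run_meta"]

log = logging.getLogger("fsomtype")

_STAGES = ("profiles", "select_k", "train", "assoc", "meta")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2^31) from the global seed."""
    idx = _STAGES.index(stage)
    child = np.random.SeedSequence(seed).spawn(len(_STAGES))[idx]
    return int(child.generate_state(1)[0] % (2 ** 31))


def run_profiles(config: RunConfig, track_path, events_path, out_dir):
    """Track + events -> profiles TSV (plus a dropped-event report)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    track = io.read_track(track_path, resolution=config.bin_size)
    events, rejected = io.read_events(events_path)
    log.info("read %d events (%d rejected)", len(events), len(rejected))
    profiles, dropped = build_profiles(track, events, config.flank_bp,
                                       config.bin_size, config.max_gap)
    write_profiles(out_dir / "profiles.tsv", profiles, stamp=config.stamp())
    report = pd.concat([rejected, dropped], ignore_index=True)
    io.write_report(out_dir / "dropped_events.tsv", report,
                    stamp=config.stamp())
    log.info("built %d profiles (%d dropped)", len(profiles), len(dropped))
    return profiles


def run_select_k(config: RunConfig, profiles_path, out_dir):
    """Profiles -> CDF-area table and selected number of clusters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = read_profiles(profiles_path)
    sel = selection.select_k(
        profiles, K=config.K, m=config.m, M=config.M,
        seed=stage_seed(config.seed, "select_k"), k_min=config.k_min,
        delta_min=config.delta_min, epochs=config.epochs,
        alpha0=config.alpha0, alphaT=config.alphaT, sigmaT=config.sigmaT,
        theta=config.theta, band_radius=config.band_radius)
    rows = [{"k": k, "area": sel.areas[k], "delta": sel.deltas[k],
             "selected": int(k == sel.k_star)} for k in sorted(sel.areas)]
    io.write_report(out_dir / "select_k.tsv", pd.DataFrame(rows),
                    stamp=config.stamp())
    log.info("selected k* = %d", sel.k_star)
    return sel


def run_typing(config: RunConfig, profiles_path, out_dir):
    """Profiles -> trained FSOM model and cluster assignments."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = read_profiles(profiles_path)
    grid = som.init_grid(config.rows, config.cols, profiles,
                         seed=stage_seed(config.seed, "train"),
                         epochs=config.epochs, alpha0=config.alpha0,
                         alphaT=config.alphaT, sigmaT=config.sigmaT,
                         theta=config.theta, band_radius=config.band_radius)
    grid, assignments = som.train(grid, profiles)
    with open(out_dir / "model.tsv", "w") as fh:
        fh.write(f"# {config.stamp()}\n")
        fh.write("row\tcol\tweights\n")
        for n in grid.neurons:
            fh.write(f"{n.row}\t{n.col}\t"
                     + ",".join(f"{w:.6g}" for w in n.weights) + "\n")
    io.write_assignments(out_dir / "assignments.tsv", assignments,
                         stamp=config.stamp())
    log.info("trained %dx%d grid on %d profiles",
             config.rows, config.cols, len(profiles))
    return grid, assignments


def run_association(config: RunConfig, assignments_path, events_path,
                    out_dir, fasta_path=None, motifs_path=None):
    """Assignments + event table (+ FASTA/motifs) -> association reports."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assignments = io.read_assignments(assignments_path)
    events, _ = io.read_events(events_path)
    rows = {}
    for ev in events:
        if ev.event_id not in assignments:
            continue
        row = dict(ev.properties)
        for name in ("psi", "fpkm", "tss_distance"):
            v = getattr(ev, name)
            if v is not None:
                row[name] = v
        rows[ev.event_id] = row
    properties = pd.DataFrame.from_dict(rows, orient="index")
    prop_rep = stats.property_report(assignments, properties,
                                     level=config.fdr_level)
    io.write_report(out_dir / "property_report.tsv", prop_rep,
                    stamp=config.stamp())
    out = [prop_rep]
    if fasta_path is not None and motifs_path is not None:
        motifs = io.read_motifs(motifs_path)
        seqs = _read_fasta(fasta_path)
        hits = {}
        for side in ("IE", "EI"):
            side_seqs = {name.split("::")[0]: s for name, s in seqs.items()
                         if name.endswith(f"::{side}")}
            if side_seqs:
                hits[side] = stats.scan_motifs(side_seqs, motifs)
        motif_rep = stats.motif_report(assignments, hits,
                                       level=config.fdr_level)
        io.write_report(out_dir / "motif_report.tsv", motif_rep,
                        stamp=config.stamp())
        out.append(motif_rep)
    return tuple(out)


def run_meta(config: RunConfig, samples: dict[str, tuple], out_dir):
    """Per-sample (assignments path, profiles path) -> super-grouping.

    Writes the dendrogram (Newick), group labels, membership-sharing
    edges and the per-sample ratio map.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples for meta-grouping")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    medians, per_sample = [], {}
    for name, (assign_path, prof_path) in sorted(samples.items()):
        assignments = io.read_assignments(assign_path)
        profiles = read_profiles(prof_path)
        med = meta.median_profiles(assignments, profiles, sample=name,
                                   min_members=config.min_members)
        medians.extend(med)
        per_sample[name] = (assignments, med)
    grouping = meta.meta_cluster(medians, n_groups=config.n_groups)
    groupings = {}
    for name, (assignments, med) in per_sample.items():
        cluster_group = {(m.row, m.col): grouping.group_of[m.key] for m in med}
        groupings[name] = {e: cluster_group[rc]
                           for e, rc in assignments.items()
                           if rc in cluster_group}
    edges, ratios = meta.membership_sharing(groupings,
                                            min_edge=config.min_edge)
    (out_dir / "dendrogram.nwk").write_text(
        meta.to_newick(grouping, medians) + "\n")
    label_rows = [{"sample": m.sample, "row": m.row, "col": m.col,
                   "group": grouping.group_of[m.key],
                   "n_members": m.n_members} for m in medians]
    io.write_report(out_dir / "supergroups.tsv", pd.DataFrame(label_rows),
                    stamp=config.stamp())
    io.write_report(out_dir / "sharing_edges.tsv", edges,
                    stamp=config.stamp())
    io.write_report(out_dir / "ratio_map.tsv", ratios, stamp=config.stamp())
    return grouping, groupings, edges, ratios


def _read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}
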