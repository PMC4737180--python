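"""File-backed run: synthetic sample -> typing -> association statistics.

Writes a bedGraph methylation track, an AS-event table (with Ψ coupled
to mean border methylation) and border FASTA with a planted FOX1 motif,
then runs the pipeline stages and prints which clusters associate with
high/low inclusion and which carry the motif.
"""

import tempfile
from pathlib import Path

from fsomtype import RunConfig
from fsomtype.pipeline import run_association, run_profiles, run_typing
from fsomtype.synthetic import default_shapes, make_track_and_events

root = Path(tempfile.mkdtemp(prefix="fsomtype_example_"))
shapes = default_shapes(noise_sd=0.1, length_jitter=2, trunc_prob=0.2)
shapes[0].planted_motif, shapes[0].motif_rate = "TGCATG", 0.8
for s in shapes[1:]:
    s.planted_motif, s.motif_rate = "TGCATG", 0.1
ds = make_track_and_events(shapes, n_events=120, genome_size=600_000,
                           seed=3, out_dir=root / "data")
(root / "motifs.tsv").write_text("FOX1\tTGCATG\n")

cfg = RunConfig(rows=2, cols=2, epochs=30, seed=3)
run_profiles(cfg, ds.track_path, ds.events_path, root / "prof")
run_typing(cfg, root / "prof/profiles.tsv", root / "model")
prop, motif = run_association(
    cfg, root / "model/assignments.tsv", ds.events_path, root / "assoc",
    fasta_path=ds.fasta_path, motifs_path=root / "motifs.tsv")

print("\nΨ inclusion per cluster vs the full event set:")
psi = prop[prop.property == "psi"]
for row in psi.itertuples():
    flag = row.direction if row.significant else "ns"
    print(f"  {row.cluster}: n={row.n:3d}  p={row.p:.2e}  q={row.q:.2e}  {flag}")

print("\nFOX1 motif enrichment (I/E side):")
for row in motif[motif.side == "IE"].itertuples():
    state = "enriched" if row.enriched else (
        "depleted" if row.depleted else "ns")
    print(f"  {row.cluster}: {row.cluster_hits}/{row.cluster_n} hits "
          f"(background {row.bg_hits}/{row.bg_n})  {state}")

# High-methylation clusters test significantly Ψ-high because the
# generator couples inclusion to mean border methylation; the flat-low
# family's cluster is FOX1-enriched because the motif was planted there
# at a 0.8 rate against a 0.1 background rate.
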