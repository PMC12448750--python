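#!/usr/bin/env python
"""Generate every synthetic input used by the downstream analyses.

Writes a 500-sequence bactofilin homolog set with planted decoys, three
surrogate peptide-bilayer systems (wild type, K4S-K7S, F2Y — identical
geometry, different charges) plus a second wild-type replicate for split
errors, a Langmuir sensorgram titration at 1% noise, and Brownian track
sets emulating the mobility series. Raw data go to scratch/ (regenerated
on demand); everything is deterministic for the seed below.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import bactomts as b
from bactomts.io import write_fasta, write_taxonomy

SEED = 1
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    # ---- homolog set -----------------------------------------------------
    hom_dir = SCRATCH / "homologs"
    hom_dir.mkdir(parents=True, exist_ok=True)
    cfg = b.HomologSetConfig(n_sequences=500, seed=SEED)
    records, taxonomy, truth = b.generate_homolog_set(cfg)
    write_fasta(records, hom_dir / "homologs.fasta")
    write_taxonomy(taxonomy, hom_dir / "taxonomy.tsv")
    write_fasta(b.generate_domain_seed_alignment(cfg),
                hom_dir / "domain_seed.fasta")
    (hom_dir / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n")
    cats = {}
    for c in truth["categories"].values():
        cats[c] = cats.get(c, 0) + 1
    print(f"[homologs] {len(records)} sequences: {cats}")

    # ---- membrane systems ------------------------------------------------
    for name, peptide, seed in [("wt", "MFSKQAKSNN", SEED),
                                ("k4s_k7s", "MFSSQASSNN", SEED),
                                ("f2y", "MYSKQAKSNN", SEED),
                                ("wt_rep2", "MFSKQAKSNN", SEED + 1)]:
        mem_dir = SCRATCH / f"membrane_{name}"
        mem_dir.mkdir(parents=True, exist_ok=True)
        mcfg = b.MembraneSystemConfig(peptide_sequence=peptide,
                                      n_frames=200,
                                      unbound_prefix_frames=10, seed=seed)
        top, traj, mtruth = b.generate_membrane_system(mcfg)
        top.to_tsv(mem_dir / "topology.tsv")
        traj.to_xyz(mem_dir / "trajectory.xyz")
        (mem_dir / "ground_truth.json").write_text(
            json.dumps(mtruth, indent=2, sort_keys=True) + "\n")
        print(f"[membrane_{name}] {top.n_atoms} atoms x {traj.n_frames} "
              f"frames, leaflet composition "
              f"{mtruth['counts_per_leaflet']}")

    # ---- sensorgrams and tracks -----------------------------------------
    kin_dir = SCRATCH / "kinetics"
    kin_dir.mkdir(parents=True, exist_ok=True)
    sg = b.generate_sensorgrams(1e4, 0.049, 1.0,
                                [1e-6, 2.5e-6, 5e-6, 1e-5, 2e-5],
                                t_assoc=120.0, t_dissoc=120.0,
                                noise_sd=0.01, seed=SEED)
    sg.to_csv(kin_dir / "sensorgrams.csv")
    print("[sensorgrams] 5 concentrations, true K_D = 4.9 uM, 1% noise")

    # diffusion series: immobile-like scaffold vs increasingly free variants
    for name, d in [("wt_like", 0.005), ("partial", 0.05),
                    ("free_like", 0.5)]:
        ts = b.generate_tracks(d, dt=0.02, n_tracks=100, n_steps=200,
                               loc_noise_sd=0.02, seed=SEED)
        ts.to_csv(kin_dir / f"tracks_{name}.csv")
        print(f"[tracks_{name}] 100 tracks x 200 steps, true D = {d} um2/s")


if __name__ == "__main__":
    main()
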