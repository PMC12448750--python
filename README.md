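# bactomts

Analysis toolkit for the membrane-targeting sequence (MTS) of bacterial
bactofilins — the short N-terminal peptide (MFSKQAKS in *Caulobacter
crescentus* BacA) through which these cytoskeletal polymers attach to the
inner face of the cytoplasmic membrane.

The package is written for people studying peripheral membrane binding of
cytoskeletal scaffolds: it provides the complete computational chain from
sequence-level conservation of the targeting peptide down to
trajectory-level statistics of a peptide at a lipid bilayer, together with
synthetic-data generators that emit every input format with machine-
readable ground truth, so each stage is testable end to end without
external databases or an MD engine.

## What it computes

**Tail conservation pipeline** (`bactomts.conservation`, `bactomts.motifs`)

Given a homolog set (FASTA + taxonomy TSV) the pipeline removes
non-bacterial entries, drops sequences whose N-terminal region contains a
predicted transmembrane helix (Kyte–Doolittle window 19, threshold 1.6),
collapses >90%-identity within-species near-duplicates, locates the
~110-residue bactofilin core domain by an ungapped log-odds profile scan
with a null-calibrated cutoff, and keeps N-terminal tails of at least 8
residues. Motifs are then discovered by ZOOPS expectation–maximization
("zero or one occurrence per sequence"): for each sequence S of length L
with m = L − W + 1 candidate sites,

    P(S) = (1 − λ) P₀(S) + (λ/m) Σⱼ Pⱼ(S),

where P₀ is a 0th-order background and Pⱼ scores the width-W window at j
under a position weight matrix θ. EM alternates site posteriors with
pseudocounted PWM / λ updates; widths 5–50 compete through a
log-likelihood-ratio objective that charges every column one bit of
per-site relative entropy. Logos are per-column heights
p(i,a)·(log₂20 − H(i)).

**Membrane trajectory statistics** (`bactomts.membrane`)

From a topology table and an extended-XYZ trajectory: per-residue density
profiles along the membrane normal (z relative to the bilayer
center of mass, midplane at 0, phosphate-peak reference), binary
per-lipid contact counts (any heavy–heavy pair within 0.5 nm under the
minimum-image convention counts once per lipid molecule), short-range
Coulomb (f·qᵢqⱼ/r, f = 138.935458 kJ·mol⁻¹·nm·e⁻²) plus Lennard-Jones
12-6 energies under a quintic potential switch on [1.0, 1.2] nm,
bound-phase detection, and two-run split errors |a − b|/2.

**Peptide biophysics** (`bactomts.biophysics`) — helical wheels
(100°/residue), residue classing, and the hydrophobic moment
µH = |Σ hₙ(cos δn, sin δn)|/N on the Eisenberg consensus scale.

**Binding and mobility fits** (`bactomts.kinetics`) — global 1:1 Langmuir
fits of biosensor titrations (association R(t) = R_eq(1 − e^(−k_obs t)),
k_obs = k_on C + k_off, R_eq = R_max C/(C + K_D); dissociation
R(t) = R₀ e^(−k_off t); K_D = k_off/k_on) with bootstrap CIs, and
diffusion coefficients from time-averaged MSD curves via
MSD = 4Dτ + b.

**Synthetic data** (`bactomts.synthetic_*`) — deterministic generators
for homolog sets (planted motif, TM decoys, near-duplicate groups,
non-bacterial entries, short tails), surrogate peptide–bilayer systems
(GLY/PG/DAG slab at 50/33/16, 128 lipids per leaflet by default,
prescribed per-residue insertion depths, i.i.d. Gaussian frames), Langmuir
sensorgrams and 2D Brownian tracks — each with a ground-truth JSON.

## Worked example

```python
import bactomts as b
import numpy as np

cfg = b.HomologSetConfig(n_sequences=500, seed=1)
records, taxonomy, truth = b.generate_homolog_set(cfg)
profile = b.DomainProfile.from_seed_alignment(
    b.generate_domain_seed_alignment(cfg))
profile.calibrate_cutoff([s for _, s in records], np.random.default_rng(1))
tails, report = b.run_filter_pipeline(records, taxonomy, profile)
print(report.removed)
motif = b.discover_motifs([t.tail for r in tails.values() for t in r],
                          n_motifs=1, seed=1)[0]
print(motif.consensus, round(motif.occupancy, 2))
```

prints

```
{'missing_taxonomy': 0, 'nonbacterial': 30, 'tm_helix': 17,
 'duplicate': 19, 'no_domain': 0, 'short_tail': 18}
MFSKKKK 0.81
```

— the 519-sequence set loses exactly its planted decoys (30 non-bacterial,
17 TM-anchored, 19 redundant strain variants, 18 mis-annotated short
tails), and ZOOPS EM recovers the planted seven-residue consensus MFSKKKK
with an occupancy estimate matching the planted 0.8.

The same steps are available from the shell:

```
bactomts simulate-homologs --n 500 --seed 1 --out scratch/homologs
bactomts mts-pipeline --fasta scratch/homologs/homologs.fasta \
    --taxonomy scratch/homologs/taxonomy.tsv \
    --profile scratch/homologs/domain_seed.fasta --out scratch/pipe
bactomts mts-motifs --tails scratch/pipe/tails_all.fasta --nmotifs 1 \
    --seed 1 --out scratch/motifs
```

The numbered scripts under `analysis/` run the full study on generated
data (01 simulate → 02 tail conservation → 03 membrane statistics →
04 amphipathicity → 05 binding/mobility) and write their tables under
`results/`.

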