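# Methods

This note documents the models, numerical choices and limitations of
`bactomts`. Everything stated here is computed by the test suite or the
analysis scripts; nothing is quoted from external data.

## Synthetic homolog sets

`generate_homolog_set` emulates what a domain-based protein retrieval
looks like after the fact: a conserved ~110-residue core flanked by
variable tails, plus the contaminant classes a curator has to remove.
Each record draws a category (non-bacterial, TM-anchored decoy,
short-tail mis-annotation, or a regular motif/plain sequence) and is
built as `tail + core + C-terminal tail`:

* the core is a fixed internal 110-residue consensus string re-sampled
  per record with per-position conservation 0.9 (each position keeps the
  consensus letter with probability 0.9, otherwise a uniformly random
  different letter). The consensus was generated once from a
  mixed, slightly polar composition and is deliberately free of
  hydrophobic runs (its maximum 19-residue Kyte–Doolittle window mean is
  1.55, below the TM threshold of 1.6);
* motif-bearing tails start with a noisy copy of the motif consensus
  (default `MFSKKKK`, conservation 0.9, occupancy 0.8) followed by filler
  drawn from a polar-biased tail composition; plain tails are
  `M` + filler. The polar filler makes chance TM windows in honest tails
  vanishingly rare, so the TM ground truth is unambiguous;
* TM decoys carry a 19–23-residue stretch of L/I/V/F inside the tail;
  the generator re-scans every emitted decoy with an independent
  brute-force hydropathy scan and asserts the plant is discoverable;
* duplicate groups model over-sequenced strains: selected motif/plain
  records spawn 1–3 extra copies with point substitutions at rate 0.05,
  capped below 9.5% of positions so near-duplicates stay above the 90%
  identity threshold *by construction* (an uncapped binomial occasionally
  crosses it);
* every non-duplicate record receives its own species; duplicates share
  their base's species. Distinct homologs of one species are not
  generated: within-species identity between independent records would
  sit near 0.7–0.8 and its upper tail would blur the planted duplicate
  ground truth.

Default sizes (500 sequences, ~3% TM decoys, 5% non-bacterial, 5% short
tails, 10 duplicate groups, tails 12–40 residues) are chosen so every
filter stage is exercised with two-digit counts while the full pipeline
runs in seconds.

What the generator does **not** emulate: homologous recombination,
indel variation in the core (the domain locator is ungapped for the same
reason), phylum-specific motif variants, or compositional drift between
lineages. Passing tests therefore demonstrate correctness of the
pipeline's decision logic and estimator, not robustness to real
evolutionary heterogeneity.

## Filtering pipeline

Stages run in a fixed order (missing taxonomy, non-bacterial, N-terminal
TM, within-species dedup, domain location, short tail), and the report
asserts `input = retained + Σ removed` on every run.

* **TM screen** — maximal runs of 19-residue window centers with mean
  Kyte–Doolittle hydropathy ≥ 1.6, expanded to full window extent.
  Removal triggers only when a segment overlaps the region N-terminal of
  the located core domain; a hydrophobic patch inside or after the core
  is not a membrane anchor for the tail under study. Window, threshold
  and scale are configurable.
* **Identity / dedup** — global alignment (match +1, mismatch 0, linear
  gap −1, Biopython `PairwiseAligner`); identity = identities / length of
  the shorter sequence, which deliberately flags fragments as duplicates
  of their full-length relatives. Greedy clustering in (length desc, id
  asc) order makes the representative choice deterministic and the
  output invariant to input order. Within-species by default; a flag
  widens it to global.
* **Domain location** — ungapped log-odds scan of a profile built from
  an ungapped seed alignment (pseudocount 0.5 per cell, background =
  pooled seed composition). The acceptance cutoff is the 99th percentile
  of max-window scores over residue-shuffled input sequences: a
  composition-preserving null, so the expected false-accept rate on
  domain-free sequences of *that* composition is ~1%. Sequences of very
  different composition are outside the null's scope — acceptable here
  because the cutoff's job is to flag shuffled/degenerate inputs, not to
  be a general-purpose domain detector.

## ZOOPS motif discovery

The likelihood is the standard zero-or-one-occurrence mixture with a
fixed 0th-order background estimated once from the pooled tails. The
letter X contributes probability 1 to any column and to the background
(i.e. it is ignored), which is also how masked sites from earlier motifs
are erased (posterior > 0.5 → window overwritten with X).

Numerics and conventions:

* PWM pseudocount 0.01 per cell. With pseudocounts the M-step is the MAP
  update under a per-column Dirichlet(1.01) prior, so the quantity EM
  increases monotonically is the penalized objective
  `ll + 0.01·Σ log θ`; `ll_trace` records that objective and a guard
  raises if it ever decreases beyond 1e-8 relative. The raw data
  likelihood can fluctuate at the ~1e-4 level near convergence — this is
  expected MAP-EM behaviour, not a bug.
* Convergence at 1e-6 relative change; 20 restarts per width seeded from
  the most frequent exact substrings (high-weight 0.7 consensus columns),
  λ₀ = 0.5. λ = 0 is a supported degenerate limit that reduces exactly to
  the background likelihood.
* **Width selection.** Total information content minus a fixed
  per-column penalty was evaluated first and rejected: because the
  background is pooled over motif *and* context positions, context
  columns carry real compositional signal whose total grows linearly
  with the site count, so any fixed (or log-n) penalty inflates the
  width once n is large — observed as rare wide junk motifs supported by
  a handful of long tails, then as `motif + filler` extensions. The
  implemented objective is scale-free:
  `obj(W) = LLR − ln2 · λ·n_used · W`, i.e. every column must carry at
  least **one bit of per-site relative entropy** against the background.
  Measured on planted data, context/filler columns carry 0.15–0.6 bits
  (including estimation noise) and 90%-conserved motif columns ≥ 1.7
  bits, so one bit sits mid-gap. Ties break to the smaller width.
* Logos use IC in bits with no small-sample correction; consensus is the
  per-column argmax with alphabetical tie-break.

An exhaustive-enumeration oracle (`zoops_hard_assignment_ll`) scores any
hard site assignment at its own MLE parameters; on tiny instances the EM
optimum dominates every enumerated assignment (tested).

## Surrogate membrane systems

Frames are i.i.d. Gaussian configurations — there is no integrator, no
momentum and no temporal correlation. This is sufficient to validate
frame-averaged statistics (densities, contacts, energies) against known
ground truth; it says nothing about kinetics, and error bars estimated
from such frames would be optimistic for a correlated real trajectory
(which is why replicate-difference split errors are used instead).

Construction: two identical leaflets of 3-bead lipids (head at ±2.0 nm
from the midplane, tail beads at ±1.2 and ±0.4 nm) on a jittered square
lattice (0.8 nm spacing by default, jitter σ = 0.05 nm), species
(GLY/PG/DAG at 50/33/16, largest-remainder rounding after
renormalization) shuffled across lattice sites by a dedicated RNG
sub-stream; a 10-residue peptide whose backbone beads sit at prescribed
depths above the midplane with per-residue Gaussian fluctuation
(default depths rise monotonically from 1.45 nm for residue 1 to
2.45 nm for residue 10, fluctuation 0.10 nm), plus optional side-chain
satellites. During the unbound prefix the peptide is held > 3 nm above
the headgroups. Two hard rules keep the surrogate physical:

* **excluded volume** — peptide beads closer than 0.35 nm to any lipid
  bead are pushed radially to 0.35 nm (i.i.d. Gaussian placement would
  otherwise produce overlaps and divergent r⁻¹² energies);
* **sequence-independent geometry** — coordinates are sampled without
  consulting the peptide sequence, so charge variants (K4S-K7S, F2Y)
  with the same seed share identical geometry and energy differences
  are purely electrostatic.

Charges: PG head −1 e, N-terminal backbone +1 e, lysine side chain +1 e;
σ/ε/mass come from a four-entry table. These are documented defaults of
a pseudo-force-field, not fitted parameters.

Per-artifact RNG streams derive from the master seed with fixed spawn
keys, so adding a generator never shifts another generator's output.

## Trajectory statistics

* Distances use the per-axis minimum-image convention (orthorhombic
  boxes only); a 27-image enumeration oracle backs the tests.
* The bilayer COM is mass-weighted over lipid atoms after making each
  molecule whole relative to its first atom; +z points toward the
  peptide-bearing leaflet's water phase.
* Densities: per-residue heavy-atom-centroid z minus COM z, 0.02 nm
  half-open bins aligned to multiples of the bin width, range expanded
  to the data; normalized so Σ density·Δz = 1 (asserted to 1e-9). The
  phosphate reference is the mode bin center of the PG headgroup
  distribution on the +z side. A Cα-like single-atom selection is
  available via `side_chains=False` in the generator.
* Contacts: a residue–lipid pair counts at most once per frame however
  many atom pairs are within 0.5 nm; species columns sum exactly to the
  total.
* Energies: Coulomb f·qᵢqⱼ/r and LJ 4ε[(σ/r)¹² − (σ/r)⁶] with
  Lorentz–Berthelot combining, multiplied by the quintic potential
  switch S = 1 − 10t³ + 15t⁴ − 6t⁵, t = (r − 1.0)/(1.2 − 1.0), zero
  beyond 1.2 nm. This is a potential switch, not the force switch a
  simulation engine would use for dynamics — irrelevant here because no
  forces are ever integrated — and reciprocal-space (long-range)
  electrostatics are omitted; reported energies are the short-range
  real-space part only.
* Bound-phase detection: first frame starting ≥ 10 consecutive frames
  (configurable) with ≥ 1 total contact; statistics refuse to run on a
  never-bound trajectory unless a start frame is forced. The
  persistence default is a conservative choice for i.i.d. frames; for
  correlated trajectories it should be increased.
* Split errors: mean (a+b)/2 and error |a−b|/2 per table entry from two
  independent replicates.

## Kinetics and mobility

The Langmuir fit is a single global nonlinear least squares over every
concentration and both phases, with parameters (k_on, k_off, R_max) on a
log scale (positivity structural, K_D = k_off/k_on an identity).
Multi-start initialization covers K_D guesses at the concentration range
extremes and median; `xtol/ftol/gtol = 1e-15` so noiseless recovery
reaches 1e-6 relative. A titration whose concentrations all sit far from
the fitted K_D is flagged non-identifiable rather than reported
silently. CIs are residual-resampling bootstrap percentiles (500
resamples, fixed seed). A per-curve k_obs linear regression is provided
as a diagnostic only.

MSD curves are time-averaged per track over all overlapping pairs at
each lag (lag 0 ≡ 0), then averaged across tracks with SD; ensemble
averaging would discard the per-track weighting and is not the default.
The diffusion fit is OLS of MSD = 4Dτ + b over lags 2–10 (2D
convention), skipping lag 1 because localization noise distorts it most
and capping at 10 because time-averaged MSD estimates decorrelate and
inflate at long lags; the intercept absorbs localization noise. Both
range and dimensionality are configurable.

## Problem sizes

Defaults throughout are the sizes the analyses and tests actually use:
500-sequence homolog sets, 16–128 lipids per leaflet with 25–200 frames,
5-concentration titrations of 241 points per phase, 100 tracks × 200
steps. The acceptance script completes in well under two minutes on one
CPU at these sizes; all are plain function arguments and scale up
linearly.

## Known limitations

* The conservation pipeline has no indel handling in the core-domain
  scan and no phylogenetic weighting; over-represented lineages beyond
  exact near-duplicates still bias motif estimation.
* The amphipathicity screen is a hydrophobic-moment computation, a
  transparent stand-in for pattern-recognition amphipathic-helix
  predictors; it classifies by a single scalar and ignores secondary-
  structure propensity.
* The surrogate membrane cannot validate time-dependent observables,
  PME electrostatics, or force-field realism; its energies are
  internally consistent (oracle-checked) but not comparable in
  magnitude to a real force field's.
* `fit_langmuir` assumes the 1:1 model it fits; mass-transport limits
  and heterogeneous ligands are out of scope and will bias apparent
  constants on real sensorgrams.
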