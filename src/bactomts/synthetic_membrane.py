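"""Stochastic surrogate peptide-bilayer systems for testing trajectory
statistics.

The generator builds a slab bilayer of GLY/PG/DAG pseudo-lipids (largest-
remainder composition rounding, identical leaflets) and a short peptide
whose residues are Gaussian-distributed around prescribed depths relative
to the bilayer center of mass. Frames are i.i.d. configurations, not
Newtonian dynamics: sufficient for frame-averaged statistics (densities,
contacts, energies) with known ground truth.

Conventions (documented defaults, not a real force field):

* each lipid has three heavy pseudo-atoms: a headgroup atom (named ``P``
  for PG, carrying -1 e) and two tail beads;
* peptide residues have one backbone heavy pseudo-atom (``BB``) and, by
  default, one side-chain satellite (``SC``); the N-terminal amino group
  contributes +1 e on residue 1's BB, lysines +1 e on their SC;
* geometry is sampled independently of the peptide sequence, so variant
  peptides (e.g. K4S-K7S) with the same seed share identical coordinates
  and differ only in charges;
* +z points from the bilayer midplane toward the peptide-bearing leaflet's
  water phase; the bilayer is centered at Lz/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Topology, Trajectory
from .synthetic_sequences import derive_rng

#: per-atom pseudo-parameters: name -> (sigma_nm, epsilon_kJmol, mass_amu)
ATOM_PARAMS = {
    "HEAD": (0.40, 0.80, 120.0),
    "TAIL": (0.40, 0.60, 180.0),
    "BB": (0.35, 0.50, 70.0),
    "SC": (0.35, 0.50, 60.0),
}

#: headgroup atom names per lipid species (PG's is phosphate-like)
HEAD_NAMES = {"GLY": "GL0", "PG": "P", "DAG": "DG0"}

#: z-offsets of the three lipid beads from the midplane (nm), upper leaflet
LIPID_BEAD_OFFSETS = (2.0, 1.2, 0.4)   # head, tail1, tail2

DEFAULT_DEPTHS = (1.45, 1.55, 1.70, 1.85, 1.95,
                  2.05, 2.15, 2.25, 2.35, 2.45)


def largest_remainder_counts(weights: dict[str, float],
                             total: int) -> dict[str, int]:
    """Apportion ``total`` among species by the largest-remainder rule.
    Weights are renormalized to sum to 1 first."""
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if np.any(w < 0):
        raise ValueError("composition weights must be >= 0")
    w = w / w.sum()
    quota = w * total
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for i in np.argsort(-rem)[: total - counts.sum()]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


@dataclass
class MembraneSystemConfig:
    lipids_per_leaflet: int = 128
    composition: dict[str, float] = field(
        default_factory=lambda: {"GLY": 0.50, "PG": 0.33, "DAG": 0.16})
    #: box (Lx, Ly, Lz) in nm; None scales the lateral size with the
    #: lipid count at 0.8 nm lattice spacing (128 lipids -> 9.6 x 9.6 x 12)
    box: tuple[float, float, float] | None = None
    peptide_sequence: str = "MFSKQAKSNN"
    residue_depths: tuple[float, ...] = DEFAULT_DEPTHS
    residue_fluct: tuple[float, ...] | float = 0.10
    n_frames: int = 200
    unbound_prefix_frames: int = 10
    lattice_jitter: float = 0.05
    min_separation: float = 0.35
    side_chains: bool = True
    frame_dt_ps: float = 100.0
    seed: int = 0

    def resolved_box(self) -> tuple[float, float, float]:
        if self.box is not None:
            return self.box
        n_side = int(np.ceil(np.sqrt(self.lipids_per_leaflet)))
        return (0.8 * n_side, 0.8 * n_side, 12.0)

    def validate(self) -> None:
        if self.lipids_per_leaflet < 1:
            raise ValueError("lipids_per_leaflet must be >= 1")
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition values must be >= 0")
        if len(self.residue_depths) != len(self.peptide_sequence):
            raise ValueError("residue_depths length must match peptide")
        box = self.resolved_box()
        n_side = int(np.ceil(np.sqrt(self.lipids_per_leaflet)))
        if box[0] / n_side < 0.55 or box[1] / n_side < 0.55:
            raise ValueError("box too small for the configured lipid count "
                             "at minimum 0.55 nm lateral spacing")
        if box[2] < 2 * LIPID_BEAD_OFFSETS[0] + 7.0:
            raise ValueError("box too short to hold an unbound peptide "
                             ">= 3 nm above the headgroups")

    def fluct_array(self) -> np.ndarray:
        n = len(self.peptide_sequence)
        if np.isscalar(self.residue_fluct):
            return np.full(n, float(self.residue_fluct))
        arr = np.asarray(self.residue_fluct, dtype=float)
        if arr.shape != (n,):
            raise ValueError("residue_fluct length must match peptide")
        return arr


def _build_topology(config: MembraneSystemConfig) -> tuple[Topology, dict]:
    counts = largest_remainder_counts(config.composition,
                                      config.lipids_per_leaflet)
    rows = []
    atom_id = mol_id = 0
    lattice_sites = []
    box = config.resolved_box()
    n_side = int(np.ceil(np.sqrt(config.lipids_per_leaflet)))
    sx = box[0] / n_side
    sy = box[1] / n_side
    species_order = [s for s in ("GLY", "PG", "DAG") for _ in range(counts[s])]
    # laterally mix the species (deterministic stream; both leaflets share
    # the same arrangement so the bilayer stays symmetric)
    shuffle_rng = derive_rng(config.seed, "membrane_topology")
    species_order = [species_order[i]
                     for i in shuffle_rng.permutation(len(species_order))]
    for leaflet in (+1, -1):
        site = 0
        for sp in species_order:
            mol_id += 1
            gx, gy = site % n_side, site // n_side
            lattice_sites.append(((gx + 0.5) * sx, (gy + 0.5) * sy, leaflet))
            names = [HEAD_NAMES[sp], "T1", "T2"]
            kinds = ["HEAD", "TAIL", "TAIL"]
            for name, kind in zip(names, kinds):
                atom_id += 1
                sig, eps, mass = ATOM_PARAMS[kind]
                charge = -1.0 if (sp == "PG" and kind == "HEAD") else 0.0
                rows.append((atom_id, mol_id, sp, 0, name, 1, charge,
                             sig, eps, mass))
            site += 1
    n_lipid_atoms = atom_id
    seq = config.peptide_sequence.upper()
    mol_id += 1
    for i, aa in enumerate(seq, start=1):
        atom_id += 1
        sig, eps, mass = ATOM_PARAMS["BB"]
        bb_charge = 1.0 if i == 1 else 0.0
        sc_charge = 1.0 if aa == "K" else 0.0
        if not config.side_chains:
            bb_charge += sc_charge
        rows.append((atom_id, mol_id, "PEPTIDE", i, "BB", 1, bb_charge,
                     sig, eps, mass))
        if config.side_chains:
            atom_id += 1
            sig, eps, mass = ATOM_PARAMS["SC"]
            rows.append((atom_id, mol_id, "PEPTIDE", i, "SC", 1, sc_charge,
                         sig, eps, mass))
    table = pd.DataFrame(rows, columns=[
        "atom_id", "mol_id", "mol_type", "res_index", "atom_name", "heavy",
        "charge_e", "sigma_nm", "epsilon_kJmol", "mass_amu"])
    table["heavy"] = table["heavy"].astype(bool)
    meta = {"lattice_sites": lattice_sites, "n_lipid_atoms": n_lipid_atoms,
            "counts_per_leaflet": counts}
    return Topology(table), meta


def _push_apart(frame: np.ndarray, n_lipid_atoms: int, box: np.ndarray,
                r_min: float, max_rounds: int = 6) -> None:
    """Excluded volume: move each peptide atom radially away from any lipid
    atom closer than ``r_min`` (minimum image), in place."""
    lip = frame[:n_lipid_atoms]
    for ai in range(n_lipid_atoms, frame.shape[0]):
        for _ in range(max_rounds):
            d = frame[ai] - lip
            d -= box * np.round(d / box)
            r = np.sqrt((d * d).sum(axis=1))
            j = int(np.argmin(r))
            if r[j] >= r_min:
                break
            unit = d[j] / r[j] if r[j] > 1e-9 else np.array([0.0, 0.0, 1.0])
            frame[ai] = lip[j] + box * np.round((frame[ai] - lip[j]) / box) \
                + unit * r_min


def generate_membrane_system(
    config: MembraneSystemConfig,
) -> tuple[Topology, Trajectory, dict]:
    """Generate topology + i.i.d.-frame trajectory + ground truth."""
    config.validate()
    rng = derive_rng(config.seed, "membrane")
    top, meta = _build_topology(config)
    lx, ly, lz = config.resolved_box()
    zc = lz / 2.0
    n_res = len(config.peptide_sequence)
    depths = np.asarray(config.residue_depths, dtype=float)
    fluct = config.fluct_array()
    n_pep_atoms = n_res * (2 if config.side_chains else 1)
    n_atoms = meta["n_lipid_atoms"] + n_pep_atoms
    head_top = zc + LIPID_BEAD_OFFSETS[0]

    coords = np.empty((config.n_frames, n_atoms, 3))
    for f in range(config.n_frames):
        # --- lipids: lattice sites + Gaussian jitter, i.i.d. per frame
        ai = 0
        for (x0, y0, leaflet) in meta["lattice_sites"]:
            for off in LIPID_BEAD_OFFSETS:
                jx, jy, jz = rng.normal(0.0, config.lattice_jitter, size=3)
                coords[f, ai] = (x0 + jx, y0 + jy,
                                 zc + leaflet * off + jz)
                ai += 1
        # --- peptide (geometry never depends on the sequence identity)
        # wide lateral wander so the peptide samples lipids of every species
        cx = lx / 2.0 + rng.normal(0.0, 1.5)
        cy = ly / 2.0 + rng.normal(0.0, 1.5)
        bound = f >= config.unbound_prefix_frames
        for i in range(n_res):
            bx = cx + (i - (n_res - 1) / 2.0) * 0.35 + rng.normal(0.0, 0.05)
            by = cy + rng.normal(0.0, 0.05)
            if bound:
                bz = zc + depths[i] + rng.normal(0.0, fluct[i]) \
                    if fluct[i] > 0 else zc + depths[i]
            else:
                # >= 3 nm above the headgroup plane during the prefix
                bz = head_top + 3.4 + 0.05 * np.abs(rng.normal())
            coords[f, ai] = (bx, by, bz)
            ai += 1
            if config.side_chains:
                coords[f, ai] = (bx + rng.normal(0.0, 0.03),
                                 by + 0.20 + rng.normal(0.0, 0.03),
                                 bz + 0.05 + rng.normal(0.0, 0.03))
                ai += 1
        if bound and config.min_separation > 0:
            _push_apart(coords[f], meta["n_lipid_atoms"],
                        np.array([lx, ly, lz]), config.min_separation)
        coords[f] = np.mod(coords[f], np.array([lx, ly, lz]))

    traj = Trajectory(
        atom_ids=top.atom_ids.copy(),
        coords=coords,
        boxes=np.tile(np.array([lx, ly, lz]), (config.n_frames, 1)),
        times=np.arange(config.n_frames) * config.frame_dt_ps,
    )
    ground_truth = {
        "residue_depths": depths.tolist(),
        "residue_fluct": fluct.tolist(),
        "unbound_prefix_frames": config.unbound_prefix_frames,
        "bilayer_center_z": zc,
        "counts_per_leaflet": meta["counts_per_leaflet"],
        "head_plane_offset": LIPID_BEAD_OFFSETS[0],
    }
    return top, traj, ground_truth
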