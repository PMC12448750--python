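"""Peptide-bilayer trajectory statistics under periodic boundaries.

Implements the frame-averaged observables for a peptide at a lipid slab:
per-residue density profiles along the membrane normal (z, relative to the
bilayer center of mass), binary per-lipid contact counts by lipid species,
short-range Coulomb + Lennard-Jones interaction energies with a potential-
switch cutoff, bound-phase detection, and two-run split errors.

Energy conventions
------------------
Pair energies use f q_i q_j / r (f = 138.935458 kJ mol^-1 nm e^-2) and
4 eps [(sigma/r)^12 - (sigma/r)^6] with Lorentz-Berthelot combining, both
multiplied by the quintic potential-switch S(r) = 1 - 10 t^3 + 15 t^4
- 6 t^5, t = (r - r_switch)/(r_cut - r_switch) on [r_switch, r_cut], and
zero beyond r_cut. Reciprocal-space (long-range) electrostatics are
omitted: the analysis never integrates forces, so only the short-range
real-space part of the interaction is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB_CONSTANT, LIPID_SPECIES
from .io import Topology, Trajectory

SPECIES_INDEX = {s: i for i, s in enumerate(LIPID_SPECIES)}


# ------------------------------------------------------------- primitives

def minimum_image_distance(p: np.ndarray, q: np.ndarray,
                           box: np.ndarray) -> float:
    """Euclidean distance between two points after per-axis minimum-image
    wrapping (orthorhombic box only)."""
    d = np.asarray(p, float) - np.asarray(q, float)
    box = np.asarray(box, float)
    d -= box * np.round(d / box)
    return float(np.sqrt((d * d).sum()))


def _min_image_delta(dx: np.ndarray, box: np.ndarray) -> np.ndarray:
    return dx - box * np.round(dx / box)


def switch_function(r: np.ndarray, switch_start: float,
                    r_cut: float) -> np.ndarray:
    """Quintic potential switch: 1 below switch_start, 0 beyond r_cut."""
    r = np.asarray(r, float)
    t = np.clip((r - switch_start) / (r_cut - switch_start), 0.0, 1.0)
    s = 1.0 - 10.0 * t**3 + 15.0 * t**4 - 6.0 * t**5
    return np.where(r >= r_cut, 0.0, s)


def unwrap_molecules(coords: np.ndarray, mol_ids: np.ndarray,
                     box: np.ndarray) -> np.ndarray:
    """Make each molecule whole by shifting every atom to the minimum
    image relative to the molecule's first atom."""
    out = coords.copy()
    for mol in np.unique(mol_ids):
        idx = np.where(mol_ids == mol)[0]
        ref = coords[idx[0]]
        out[idx] = ref + _min_image_delta(coords[idx] - ref, box)
    return out


def bilayer_com_z(frame_coords: np.ndarray, topology: Topology,
                  box: np.ndarray) -> float:
    """Mass-weighted mean z of all lipid atoms, after making each lipid
    molecule whole; the result is wrapped into [0, Lz)."""
    mask = topology.lipid_mask()
    coords = unwrap_molecules(frame_coords[mask], topology.mol_ids[mask],
                              np.asarray(box, float))
    masses = topology.masses[mask]
    com = float((coords[:, 2] * masses).sum() / masses.sum())
    return com % float(box[2])


# --------------------------------------------------- contacts and energies

def _peptide_lipid_layout(topology: Topology):
    """Index arrays shared by the contact and energy kernels."""
    pep = np.where(topology.peptide_mask() & topology.heavy)[0]
    lip = np.where(topology.lipid_mask() & topology.heavy)[0]
    res = topology.res_index[pep].astype(int)
    residues = np.unique(res)
    res_pos = np.searchsorted(residues, res)
    lip_mol = topology.mol_ids[lip]
    mols, lip_mol_pos = np.unique(lip_mol, return_inverse=True)
    # species of each lipid molecule
    mol_species = np.empty(len(mols), dtype=int)
    for k, m in enumerate(mols):
        sp = topology.mol_types[lip][lip_mol == m][0]
        mol_species[k] = SPECIES_INDEX[sp]
    return pep, lip, residues, res_pos, mols, lip_mol_pos, mol_species


def _pair_distances(coords: np.ndarray, pep: np.ndarray, lip: np.ndarray,
                    box: np.ndarray) -> np.ndarray:
    d = coords[pep][:, None, :] - coords[lip][None, :, :]
    d = _min_image_delta(d, box)
    return np.sqrt((d * d).sum(axis=-1))


def contacts_per_frame(trajectory: Trajectory, topology: Topology,
                       cutoff: float = 0.5, start_frame: int = 1,
                       ) -> np.ndarray:
    """Per-frame binary-per-lipid contact counts.

    Returns an array (n_frames_used, n_residues, 3): for each frame and
    residue, the number of lipid molecules of each species with at least
    one heavy-heavy atom pair within ``cutoff`` (minimum image). Frames
    are 1-based; ``start_frame`` selects frames >= start_frame.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pep, lip, residues, res_pos, mols, lip_mol_pos, mol_species = \
        _peptide_lipid_layout(topology)
    frames = range(start_frame - 1, trajectory.n_frames)
    out = np.zeros((len(frames), len(residues), 3))
    for fi, f in enumerate(frames):
        r = _pair_distances(trajectory.coords[f], pep, lip,
                            trajectory.boxes[f])
        close = r <= cutoff
        # collapse to (residue, lipid molecule) indicators
        ind = np.zeros((len(residues), len(mols)), dtype=bool)
        np.logical_or.at(ind, (res_pos[:, None].repeat(len(lip), 1)[close],
                               np.broadcast_to(lip_mol_pos,
                                               r.shape)[close]), True)
        for s in range(3):
            out[fi, :, s] = ind[:, mol_species == s].sum(axis=1)
    return out


@dataclass
class ContactTable:
    """Mean contacts per frame, per residue and lipid species."""

    residues: np.ndarray
    mean: np.ndarray          # (n_res, 3) species order GLY, PG, DAG
    n_frames: int
    error: np.ndarray | None = None

    @property
    def total(self) -> np.ndarray:
        return self.mean.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean, columns=list(LIPID_SPECIES))
        df.insert(0, "residue", self.residues)
        df["total"] = self.total
        if self.error is not None:
            for i, s in enumerate(LIPID_SPECIES):
                df[f"{s}_err"] = self.error[:, i]
            df["total_err"] = self.error.sum(axis=1)
        return df


def count_contacts(trajectory: Trajectory, topology: Topology,
                   cutoff: float = 0.5, start_frame: int = 1) -> ContactTable:
    """Frame-averaged binary-per-lipid contact counts (see
    ``contacts_per_frame`` for the criterion)."""
    per_frame = contacts_per_frame(trajectory, topology, cutoff, start_frame)
    residues = np.unique(
        topology.res_index[topology.peptide_mask() & topology.heavy])
    return ContactTable(residues=residues.astype(int),
                        mean=per_frame.mean(axis=0),
                        n_frames=per_frame.shape[0])


def energies_per_frame(trajectory: Trajectory, topology: Topology,
                       r_cut: float = 1.2, switch_start: float = 1.0,
                       start_frame: int = 1) -> np.ndarray:
    """Per-frame short-range interaction energies.

    Returns (n_frames_used, n_residues, 3 species, 2 terms) in kJ/mol,
    terms ordered (coulomb, lj).
    """
    pep, lip, residues, res_pos, mols, lip_mol_pos, mol_species = \
        _peptide_lipid_layout(topology)
    q = topology.charges
    sig = topology.sigma
    eps = topology.epsilon
    qq = q[pep][:, None] * q[lip][None, :] * COULOMB_CONSTANT
    sig_ij = 0.5 * (sig[pep][:, None] + sig[lip][None, :])
    eps_ij = np.sqrt(eps[pep][:, None] * eps[lip][None, :])
    species_of_pair = mol_species[lip_mol_pos]
    frames = range(start_frame - 1, trajectory.n_frames)
    out = np.zeros((len(frames), len(residues), 3, 2))
    for fi, f in enumerate(frames):
        r = _pair_distances(trajectory.coords[f], pep, lip,
                            trajectory.boxes[f])
        s = switch_function(r, switch_start, r_cut)
        with np.errstate(divide="ignore"):
            coul = np.where(r > 0, qq / np.where(r > 0, r, 1.0), 0.0) * s
        sr6 = (sig_ij / np.where(r > 0, r, 1.0)) ** 6
        lj = 4.0 * eps_ij * (sr6 * sr6 - sr6) * s
        for term, mat in enumerate((coul, lj)):
            np.add.at(out[fi, :, :, term],
                      (res_pos[:, None].repeat(len(lip), 1).ravel(),
                       np.broadcast_to(species_of_pair, r.shape).ravel()),
                      mat.ravel())
    return out


@dataclass
class EnergyTable:
    """Mean per-residue interaction energies by species and term."""

    residues: np.ndarray
    mean: np.ndarray          # (n_res, 3, 2): species x (coulomb, lj)
    n_frames: int
    error: np.ndarray | None = None

    def combined(self) -> np.ndarray:
        """(n_res, 3) coulomb + lj per species."""
        return self.mean.sum(axis=2)

    def total(self) -> np.ndarray:
        """(n_res,) combined energy summed over species."""
        return self.combined().sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, res in enumerate(self.residues):
            row = {"residue": int(res)}
            for s_i, s in enumerate(LIPID_SPECIES):
                row[f"{s}_coulomb"] = self.mean[i, s_i, 0]
                row[f"{s}_lj"] = self.mean[i, s_i, 1]
                row[f"{s}_combined"] = self.mean[i, s_i].sum()
            row["total_combined"] = self.mean[i].sum()
            rows.append(row)
        return pd.DataFrame(rows)


def interaction_energies(trajectory: Trajectory, topology: Topology,
                         r_cut: float = 1.2, switch_start: float = 1.0,
                         start_frame: int = 1) -> EnergyTable:
    per_frame = energies_per_frame(trajectory, topology, r_cut, switch_start,
                                   start_frame)
    residues = np.unique(
        topology.res_index[topology.peptide_mask() & topology.heavy])
    return EnergyTable(residues=residues.astype(int),
                       mean=per_frame.mean(axis=0),
                       n_frames=per_frame.shape[0])


# ------------------------------------------------------ bound-phase finder

def detect_bound_phase(trajectory: Trajectory, topology: Topology,
                       cutoff: float = 0.5, contact_min: int = 1,
                       persistence_frames: int = 10) -> int | None:
    """First 1-based frame index starting a run of at least
    ``persistence_frames`` consecutive frames whose total peptide-lipid
    contact count is >= ``contact_min``; None when never bound."""
    per_frame = contacts_per_frame(trajectory, topology, cutoff,
                                   start_frame=1)
    totals = per_frame.sum(axis=(1, 2))
    ok = totals >= contact_min
    count = 0
    for f, flag in enumerate(ok):
        count = count + 1 if flag else 0
        if count >= persistence_frames:
            return f - persistence_frames + 2   # 1-based start of the run
    return None


# -------------------------------------------------------- density profiles

@dataclass
class DensityProfile:
    residue: int
    bin_edges: np.ndarray       # nm, relative to bilayer COM
    density: np.ndarray         # normalized: sum(density * dz) = 1
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_z(self) -> float:
        dz = np.diff(self.bin_edges)
        return float((self.bin_centers * self.density * dz).sum())


def _aligned_edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def residue_density_profiles(trajectory: Trajectory, topology: Topology,
                             bin_width: float = 0.02, start_frame: int = 1,
                             ) -> tuple[list[DensityProfile], float]:
    """Per-residue histograms of heavy-atom-centroid z minus the bilayer
    COM z (minimum-image difference), over frames >= ``start_frame``
    (1-based), plus the phosphate peak position.

    The phosphate peak is the mode bin center of the PG headgroup-
    phosphate distribution on the peptide-bearing (+z) side.
    """
    pep_heavy = topology.peptide_mask() & topology.heavy
    residues = np.unique(topology.res_index[pep_heavy]).astype(int)
    frames = list(range(start_frame - 1, trajectory.n_frames))
    rel = {r: [] for r in residues}
    phos = []
    is_phos = (topology.mol_types == "PG") & (topology.table["atom_name"]
                                              == "P").to_numpy()
    for f in frames:
        box = trajectory.boxes[f]
        com = bilayer_com_z(trajectory.coords[f], topology, box)
        for r in residues:
            mask = pep_heavy & (topology.res_index == r)
            zs = trajectory.coords[f][mask, 2]
            dz = _min_image_delta(zs - com, box[2])
            centroid = float(np.mean(dz))
            rel[r].append(centroid)
        pz = _min_image_delta(trajectory.coords[f][is_phos, 2] - com, box[2])
        phos.extend(pz.tolist())
    profiles = []
    for r in residues:
        vals = np.asarray(rel[r])
        edges = _aligned_edges(vals, bin_width)
        hist, _ = np.histogram(vals, bins=edges)
        density = hist / (hist.sum() * bin_width)
        profiles.append(DensityProfile(residue=int(r), bin_edges=edges,
                                       density=density,
                                       n_frames=len(frames)))
    phos = np.asarray(phos)
    upper = phos[phos >= 0]
    side = upper if upper.size else phos
    edges = _aligned_edges(side, bin_width)
    hist, _ = np.histogram(side, bins=edges)
    peak = float(0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1]))
    return profiles, peak


# ------------------------------------------------------------ split errors

def split_error(stat_a: np.ndarray, stat_b: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Two-run statistics: reported mean (a+b)/2 and error |a-b|/2 per
    entry (the convention for two independent replicate simulations)."""
    a = np.asarray(stat_a, float)
    b = np.asarray(stat_b, float)
    if a.shape != b.shape:
        raise ValueError("statistics must have identical shapes")
    return 0.5 * (a + b), 0.5 * np.abs(a - b)
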