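"""Tests of trajectory statistics: distances, COM, contacts, energies,
densities, bound-phase detection and split errors."""

import numpy as np
import pandas as pd
import pytest

import bactomts as b
from bactomts.constants import COULOMB_CONSTANT
from bactomts.membrane import switch_function
from conftest import brute_force_contacts, brute_force_energies


# ------------------------------------------------------- minimum image

def test_minimum_image_basics():
    box = (10.0, 10.0, 10.0)
    assert b.minimum_image_distance((1, 2, 3), (1, 2, 3), box) == 0.0
    assert b.minimum_image_distance((0.1, 0, 0), (9.9, 0, 0), box) == \
        pytest.approx(0.2)


def test_minimum_image_matches_27_image_enumeration():
    rng = np.random.default_rng(0)
    box = np.array([3.0, 4.0, 5.0])
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)])
    for _ in range(200):
        p = rng.uniform(0, box)
        q = rng.uniform(0, box)
        brute = min(np.linalg.norm(p - (q + s * box)) for s in shifts)
        assert b.minimum_image_distance(p, q, box) == pytest.approx(brute)


# ---------------------------------------------------------- bilayer COM

def _two_atom_topology():
    rows = [
        (1, 1, "GLY", 0, "GL0", True, 0.0, 0.4, 0.8, 100.0),
        (2, 2, "GLY", 0, "GL0", True, 0.0, 0.4, 0.8, 100.0),
    ]
    return b.Topology(pd.DataFrame(rows, columns=[
        "atom_id", "mol_id", "mol_type", "res_index", "atom_name", "heavy",
        "charge_e", "sigma_nm", "epsilon_kJmol", "mass_amu"]))


def test_equal_mass_two_atom_bilayer_com():
    top = _two_atom_topology()
    coords = np.array([[0, 0, 1.0], [0, 0, 3.0]])
    assert b.bilayer_com_z(coords, top, (5, 5, 10)) == pytest.approx(2.0)


def test_com_invariant_under_periodic_translation(small_membrane):
    _, top, traj, _ = small_membrane
    box = traj.boxes[0]
    c0 = b.bilayer_com_z(traj.coords[0], top, box)
    shifted = np.mod(traj.coords[0] + box, box)   # whole-box translation
    c1 = b.bilayer_com_z(shifted, top, box)
    assert c1 == pytest.approx(c0, abs=1e-9)


# -------------------------------------------------------------- contacts

def test_contact_criterion_at_the_cutoff():
    rows = [
        (1, 1, "PG", 0, "P", True, -1.0, 0.4, 0.8, 120.0),
        (2, 1, "PG", 0, "T1", True, 0.0, 0.4, 0.6, 180.0),
        (3, 2, "PEPTIDE", 1, "BB", True, 1.0, 0.35, 0.5, 70.0),
        (4, 2, "PEPTIDE", 1, "SC", True, 0.0, 0.35, 0.5, 60.0),
    ]
    top = b.Topology(pd.DataFrame(rows, columns=[
        "atom_id", "mol_id", "mol_type", "res_index", "atom_name", "heavy",
        "charge_e", "sigma_nm", "epsilon_kJmol", "mass_amu"]))

    def traj_with(dist_bb, dist_sc):
        coords = np.array([[[1.0, 1.0, 1.0], [1.0, 1.0, 3.0],
                            [1.0 + dist_bb, 1.0, 1.0],
                            [1.0 + dist_sc, 1.0, 1.0]]])
        return b.Trajectory(np.array([1, 2, 3, 4]), coords,
                            np.array([[8.0, 8.0, 8.0]]), np.array([0.0]))

    # one atom at 0.49 nm -> 1 contact; at 0.51 nm -> 0
    t = b.count_contacts(traj_with(0.49, 2.0), top)
    assert t.mean[0, 1] == 1.0          # PG column
    t = b.count_contacts(traj_with(0.51, 2.0), top)
    assert t.mean[0, 1] == 0.0
    # two atoms of the residue within the cutoff of the same lipid:
    # still a single contact
    t = b.count_contacts(traj_with(0.49, 0.45), top)
    assert t.mean[0, 1] == 1.0


def test_contacts_match_brute_force_oracle(small_membrane):
    _, top, traj, _ = small_membrane
    fast = b.count_contacts(traj, top, start_frame=6)
    frames = range(5, traj.n_frames)
    slow = np.mean([brute_force_contacts(traj.coords[f], top,
                                         traj.boxes[f])
                    for f in frames], axis=0)
    assert np.array_equal(fast.mean, slow)
    # decomposition identity: total = GLY + PG + DAG
    assert np.allclose(fast.total, fast.mean.sum(axis=1), atol=1e-9)


def test_contacts_invariant_under_lipid_relabeling(small_membrane):
    _, top, traj, _ = small_membrane
    base = b.count_contacts(traj, top, start_frame=6).mean
    # swap two same-species lipid molecules (atom blocks)
    table = top.table.copy().reset_index(drop=True)
    gly_mols = table.loc[table["mol_type"] == "GLY", "mol_id"].unique()[:2]
    a, bb = gly_mols
    remap = {a: bb, bb: a}
    table["mol_id"] = table["mol_id"].map(lambda m: remap.get(m, m))
    swapped = b.count_contacts(traj, b.Topology(table),
                               start_frame=6).mean
    assert np.array_equal(base, swapped)


# -------------------------------------------------------------- energies

def test_point_charge_coulomb_closed_form():
    # +1 e and -1 e at 0.5 nm, inside the switch region: -277.87 kJ/mol
    rows = [
        (1, 1, "PG", 0, "P", True, -1.0, 0.4, 0.0, 120.0),
        (2, 2, "PEPTIDE", 1, "BB", True, 1.0, 0.4, 0.0, 70.0),
    ]
    top = b.Topology(pd.DataFrame(rows, columns=[
        "atom_id", "mol_id", "mol_type", "res_index", "atom_name", "heavy",
        "charge_e", "sigma_nm", "epsilon_kJmol", "mass_amu"]))
    coords = np.array([[[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]])
    traj = b.Trajectory(np.array([1, 2]), coords,
                        np.array([[8.0, 8.0, 8.0]]), np.array([0.0]))
    table = b.interaction_energies(traj, top)
    assert table.mean[0, 1, 0] == pytest.approx(-COULOMB_CONSTANT / 0.5)
    assert table.mean[0, 1, 0] == pytest.approx(-277.87, abs=0.01)
    assert table.mean[0, 1, 1] == 0.0


def test_lj_closed_forms_and_cutoff():
    sig, eps = 0.35, 0.6

    def energy_at(r):
        rows = [
            (1, 1, "GLY", 0, "GL0", True, 0.0, sig, eps, 100.0),
            (2, 2, "PEPTIDE", 1, "BB", True, 0.0, sig, eps, 70.0),
        ]
        top = b.Topology(pd.DataFrame(rows, columns=[
            "atom_id", "mol_id", "mol_type", "res_index", "atom_name",
            "heavy", "charge_e", "sigma_nm", "epsilon_kJmol", "mass_amu"]))
        coords = np.array([[[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]]])
        traj = b.Trajectory(np.array([1, 2]), coords,
                            np.array([[10.0, 10.0, 10.0]]),
                            np.array([0.0]))
        return b.interaction_energies(traj, top).mean[0, 0, 1]

    assert energy_at(sig) == pytest.approx(0.0, abs=1e-12)
    assert energy_at(2 ** (1 / 6) * sig) == pytest.approx(-eps)
    assert energy_at(1.25) == 0.0               # beyond the 1.2 nm cutoff


def test_switch_function_shape():
    assert switch_function(np.array([0.5]), 1.0, 1.2)[0] == 1.0
    assert switch_function(np.array([1.2]), 1.0, 1.2)[0] == 0.0
    mid = switch_function(np.array([1.1]), 1.0, 1.2)[0]
    assert 0.0 < mid < 1.0
    r = np.linspace(0.9, 1.25, 50)
    s = switch_function(r, 1.0, 1.2)
    assert np.all(np.diff(s) <= 1e-12)          # monotone decrease


def test_energies_match_brute_force_oracle(small_membrane):
    _, top, traj, _ = small_membrane
    fast = b.interaction_energies(traj, top, start_frame=6)
    frames = range(5, traj.n_frames)
    slow = np.mean([brute_force_energies(traj.coords[f], top,
                                         traj.boxes[f])
                    for f in frames], axis=0)
    denom = np.maximum(np.abs(slow), 1e-12)
    assert np.all(np.abs(fast.mean - slow) / denom < 1e-9)


def test_energy_species_columns_sum_to_total(small_membrane):
    _, top, traj, _ = small_membrane
    table = b.interaction_energies(traj, top, start_frame=6)
    df = table.to_frame()
    combined = df[["GLY_combined", "PG_combined", "DAG_combined"]].sum(axis=1)
    assert np.allclose(combined, df["total_combined"], atol=1e-9)
    assert np.allclose(table.combined(),
                       table.mean[:, :, 0] + table.mean[:, :, 1])


def test_charge_mutation_weakens_pg_coulomb_under_identical_geometry():
    kw = dict(lipids_per_leaflet=16, box=(4.8, 4.8, 12.0), n_frames=60,
              unbound_prefix_frames=5, seed=31)
    top_wt, traj_wt, _ = b.generate_membrane_system(
        b.MembraneSystemConfig(peptide_sequence="MFSKQAKSNN", **kw))
    top_mut, traj_mut, _ = b.generate_membrane_system(
        b.MembraneSystemConfig(peptide_sequence="MFSSQASSNN", **kw))
    assert np.array_equal(traj_wt.coords, traj_mut.coords)
    e_wt = b.interaction_energies(traj_wt, top_wt, start_frame=6)
    e_mut = b.interaction_energies(traj_mut, top_mut, start_frame=6)
    for res in (4, 7):
        i = res - 1
        assert e_wt.mean[i, 1, 0] < e_mut.mean[i, 1, 0]


# ----------------------------------------------------------- bound phase

def test_bound_phase_detection(small_membrane):
    cfg, top, traj, _ = small_membrane
    first = b.detect_bound_phase(traj, top)
    assert first == cfg.unbound_prefix_frames + 1
    assert b.detect_bound_phase(traj, top, persistence_frames=1) == first


def test_never_bound_returns_none():
    cfg = b.MembraneSystemConfig(
        lipids_per_leaflet=9, box=(4.8, 4.8, 12.0), n_frames=12,
        unbound_prefix_frames=12, seed=2)
    top, traj, _ = b.generate_membrane_system(cfg)
    assert b.detect_bound_phase(traj, top) is None


# --------------------------------------------------------------- density

def test_density_profiles_normalized_and_ordered(small_membrane):
    cfg, top, traj, truth = small_membrane
    profiles, peak = b.residue_density_profiles(traj, top, start_frame=6)
    for p in profiles:
        integral = float((p.density * np.diff(p.bin_edges)).sum())
        assert integral == pytest.approx(1.0, abs=1e-9)
    means = [p.mean_z() for p in profiles]
    assert np.all(np.diff(means) > 0)       # monotone tilt toward water
    assert peak == pytest.approx(truth["head_plane_offset"], abs=0.1)


def test_pinned_residue_density_collapses_to_one_bin():
    cfg = b.MembraneSystemConfig(
        lipids_per_leaflet=9, box=(4.8, 4.8, 12.0), n_frames=12,
        unbound_prefix_frames=0, residue_fluct=0.0, min_separation=0.0,
        lattice_jitter=0.0,
        residue_depths=tuple([-1.0] * 10), side_chains=False, seed=4)
    top, traj, _ = b.generate_membrane_system(cfg)
    profiles, _ = b.residue_density_profiles(traj, top)
    for p in profiles:
        occupied = p.density > 0
        assert occupied.sum() == 1
        center = p.bin_centers[occupied][0]
        assert abs(center - (-1.0)) <= 0.02


def test_gaussian_depth_recovered_within_monte_carlo_error():
    n_frames = 400
    cfg = b.MembraneSystemConfig(
        lipids_per_leaflet=9, box=(4.8, 4.8, 12.0), n_frames=n_frames,
        unbound_prefix_frames=0, residue_fluct=0.1, min_separation=0.0,
        residue_depths=tuple([-0.8] * 10), side_chains=False, seed=5)
    top, traj, _ = b.generate_membrane_system(cfg)
    profiles, _ = b.residue_density_profiles(traj, top)
    se = 0.1 / np.sqrt(n_frames)
    for p in profiles:
        assert abs(p.mean_z() - (-0.8)) < 3 * se + 0.02


# ------------------------------------------------------------ split error

def test_split_error_identities():
    a = np.array([4.0, 1.0])
    c = np.array([2.0, 1.0])
    mean, err = b.split_error(a, c)
    assert np.array_equal(mean, [3.0, 1.0])
    assert np.array_equal(err, [1.0, 0.0])
    mean2, err2 = b.split_error(c, a)
    assert np.array_equal(mean, mean2)
    assert np.array_equal(err, err2)
    _, zero = b.split_error(a, a)
    assert np.array_equal(zero, [0.0, 0.0])
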