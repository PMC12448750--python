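import numpy as np
import pytest

import bactomts as b


@pytest.fixture(scope="session")
def small_membrane():
    """Small surrogate peptide-bilayer system shared across tests."""
    cfg = b.MembraneSystemConfig(
        lipids_per_leaflet=16, box=(4.8, 4.8, 12.0), n_frames=40,
        unbound_prefix_frames=5, seed=11)
    top, traj, truth = b.generate_membrane_system(cfg)
    return cfg, top, traj, truth


@pytest.fixture(scope="session")
def homolog_set():
    """Mixed 300-sequence homolog set with every decoy class planted."""
    cfg = b.HomologSetConfig(n_sequences=300, seed=5)
    records, taxonomy, truth = b.generate_homolog_set(cfg)
    return cfg, records, taxonomy, truth


@pytest.fixture(scope="session")
def domain_profile(homolog_set):
    cfg, records, _, _ = homolog_set
    profile = b.DomainProfile.from_seed_alignment(
        b.generate_domain_seed_alignment(cfg))
    profile.calibrate_cutoff([s for _, s in records],
                             np.random.default_rng(0))
    return profile


def brute_force_contacts(coords, topology, box, cutoff=0.5):
    """O(N^2) reference: per (residue, species) binary-per-lipid contact
    counts for one frame."""
    from bactomts.constants import LIPID_SPECIES
    res_ids = sorted(set(
        topology.res_index[topology.peptide_mask() & topology.heavy]))
    out = np.zeros((len(res_ids), 3))
    lipid_mols = sorted(set(topology.mol_ids[topology.lipid_mask()]))
    for ri, res in enumerate(res_ids):
        pep_idx = np.where(topology.peptide_mask() & topology.heavy
                           & (topology.res_index == res))[0]
        for mol in lipid_mols:
            lip_idx = np.where((topology.mol_ids == mol)
                               & topology.heavy)[0]
            sp = topology.mol_types[lip_idx[0]]
            touching = False
            for i in pep_idx:
                for j in lip_idx:
                    if b.minimum_image_distance(coords[i], coords[j],
                                                box) <= cutoff:
                        touching = True
                        break
                if touching:
                    break
            if touching:
                out[ri, LIPID_SPECIES.index(sp)] += 1
    return out


def brute_force_energies(coords, topology, box, r_cut=1.2,
                         switch_start=1.0):
    """O(N^2) reference: per (residue, species, term) energies for one
    frame, pure-python pair loop."""
    from bactomts.constants import COULOMB_CONSTANT, LIPID_SPECIES
    from bactomts.membrane import switch_function
    res_ids = sorted(set(
        topology.res_index[topology.peptide_mask() & topology.heavy]))
    out = np.zeros((len(res_ids), 3, 2))
    q, sig, eps = topology.charges, topology.sigma, topology.epsilon
    lip_idx = np.where(topology.lipid_mask() & topology.heavy)[0]
    for ri, res in enumerate(res_ids):
        pep_idx = np.where(topology.peptide_mask() & topology.heavy
                           & (topology.res_index == res))[0]
        for i in pep_idx:
            for j in lip_idx:
                r = b.minimum_image_distance(coords[i], coords[j], box)
                if r >= r_cut or r == 0:
                    continue
                s = float(switch_function(np.array([r]), switch_start,
                                          r_cut)[0])
                sp = LIPID_SPECIES.index(topology.mol_types[j])
                out[ri, sp, 0] += COULOMB_CONSTANT * q[i] * q[j] / r * s
                sij = 0.5 * (sig[i] + sig[j])
                eij = np.sqrt(eps[i] * eps[j])
                sr6 = (sij / r) ** 6
                out[ri, sp, 1] += 4 * eij * (sr6 ** 2 - sr6) * s
    return out
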