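"""Synthetic bactofilin homolog sets with machine-readable ground truth.

The generator emulates the salient features of a UniProt-style bactofilin
domain retrieval: a bacterial/non-bacterial mixture, a minority of decoys
carrying an N-terminal transmembrane (TM) helix, groups of >90%-identity
near-duplicates within single species, a conserved ~110-residue core domain
flanked by variable tails, and an N-terminal membrane-targeting motif
planted with configurable per-position conservation.

Every record is assigned to exactly one ground-truth category:

``motif``        bacterial, carries a noisy copy of the motif consensus at
                 the start of its N-terminal tail;
``plain``        bacterial, motif-free tail (controlled by motif_occupancy);
``nonbacterial`` archaeal/eukaryotic decoy, removed by the taxonomy filter;
``tm_decoy``     bacterial, N-terminal tail contains a >=19-residue strongly
                 hydrophobic stretch;
``short_tail``   bacterial, tail shorter than 8 residues;
``duplicate``    extra within-species near-copy of a motif/plain base record.

Each non-duplicate record lives in its own species; duplicate copies share
the species of their base record, mirroring over-sequencing of strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AA_ALPHABET, KYTE_DOOLITTLE

#: fixed internal core-domain consensus (110 residues); its maximum
#: 19-residue Kyte-Doolittle window mean is 1.55, below the TM threshold.
DOMAIN_CONSENSUS = (
    "YRLNWARNTETNGEINFYSLSTEGTGSIESNPKQAILGGAIVRFPMVVNIKLAAAGGNGV"
    "LNANIERTVKESTMAILTKRAGRVTTIDNSIAHKGSKSNGQWEFAETKFA"
)

#: polar-biased tail composition; strongly hydrophobic letters are rare so
#: that chance TM-like windows in filler tails are vanishingly unlikely
TAIL_COMPOSITION = {
    "A": 6, "C": 1, "D": 8, "E": 9, "F": 1, "G": 8, "H": 3, "I": 1, "K": 9,
    "L": 2, "M": 1, "N": 8, "P": 6, "Q": 7, "R": 8, "S": 10, "T": 8, "V": 2,
    "W": 1, "Y": 2,
}

#: residues used for planted transmembrane stretches
TM_RESIDUES = "LIVF"

DEFAULT_PHYLA = {
    "Pseudomonadota": 0.45,
    "Bacteroidota": 0.20,
    "Bacillota": 0.15,
    "Spirochaetota": 0.10,
    "Thermodesulfobacteriota": 0.10,
}

NONBACTERIAL_TAXA = [
    ("Archaea", "Euryarchaeota"),
    ("Archaea", "Thermoproteota"),
    ("Eukaryota", "Ascomycota"),
]

#: documented sub-stream keys so adding a generator never shifts another's
#: output (one RNG stream per artifact, derived from the master seed)
STREAM_KEYS = {
    "homologs": 11,
    "domain_seed": 12,
    "membrane": 21,
    "membrane_topology": 22,
    "sensorgrams": 31,
    "tracks": 41,
}


def derive_rng(seed: int, artifact: str) -> np.random.Generator:
    """Deterministic per-artifact RNG stream from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(STREAM_KEYS[artifact],)))


@dataclass
class HomologSetConfig:
    n_sequences: int = 500
    phylum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLA))
    motif_consensus: str = "MFSKKKK"
    motif_conservation: float = 0.9
    motif_occupancy: float = 0.8
    frac_nonbacterial: float = 0.05
    frac_tm_decoys: float = 0.03
    frac_short_tail: float = 0.05
    n_duplicate_groups: int = 10
    duplicate_group_size: tuple[int, int] = (2, 4)   # inclusive range
    duplicate_sub_rate: float = 0.05
    domain_conservation: float = 0.9
    domain_length: int = 110
    tail_length_range: tuple[int, int] = (12, 40)
    cterm_length_range: tuple[int, int] = (0, 15)
    seed: int = 0

    def validate(self) -> None:
        probs = [self.motif_conservation, self.motif_occupancy,
                 self.frac_nonbacterial, self.frac_tm_decoys,
                 self.frac_short_tail, self.duplicate_sub_rate]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not self.motif_conservation > 0:
            raise ValueError("motif_conservation must be in (0, 1]")
        total = sum(self.phylum_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError("phylum_weights must sum to 1")
        if self.tail_length_range[0] < len(self.motif_consensus):
            raise ValueError(
                "tail_length_range lower bound must be >= motif length")
        if self.duplicate_sub_rate >= 0.10:
            raise ValueError("duplicate_sub_rate must be < 0.10 so that "
                             "near-duplicates stay above 90% identity")


def _tail_probs() -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(TAIL_COMPOSITION))
    p = np.array([TAIL_COMPOSITION[a] for a in letters], float)
    return letters, p / p.sum()


def _sample_tail(rng: np.random.Generator, n: int) -> str:
    letters, p = _tail_probs()
    return "".join(rng.choice(letters, size=n, p=p)) if n else ""


def _noisy_copy(rng: np.random.Generator, template: str,
                conservation: float) -> str:
    """Per-position: keep template letter w.p. ``conservation``, else a
    uniformly random *different* letter."""
    out = []
    for c in template:
        if rng.random() < conservation:
            out.append(c)
        else:
            alt = [a for a in AA_ALPHABET if a != c]
            out.append(alt[rng.integers(len(alt))])
    return "".join(out)


def _substitute(rng: np.random.Generator, seq: str, rate: float,
                max_frac: float = 0.095) -> str:
    """Point-substitute ~Binomial(len, rate) positions, capped below
    ``max_frac`` of the length so near-duplicates stay above 90%
    identity by construction."""
    n = len(seq)
    k = min(int(rng.binomial(n, rate)), int(np.floor(max_frac * n)))
    out = list(seq)
    for i in rng.choice(n, size=k, replace=False):
        c = out[i]
        alt = [a for a in AA_ALPHABET if a != c]
        out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def tm_windows(sequence: str, window: int = 19,
               threshold: float = 1.6) -> list[int]:
    """Brute-force scan: 0-based start positions of windows whose mean
    Kyte-Doolittle hydropathy is >= threshold (ground-truth oracle)."""
    vals = [KYTE_DOOLITTLE.get(c, 0.0) for c in sequence]
    hits = []
    for i in range(len(vals) - window + 1):
        if sum(vals[i:i + window]) / window >= threshold:
            hits.append(i)
    return hits


def generate_homolog_set(
    config: HomologSetConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame, dict]:
    """Generate a homolog set: FASTA-ready records, taxonomy table, ground
    truth dictionary (categories, planted motif sites, duplicate groups,
    true domain intervals)."""
    config.validate()
    rng = derive_rng(config.seed, "homologs")
    phyla = sorted(config.phylum_weights)
    pw = np.array([config.phylum_weights[p] for p in phyla])
    pw = pw / pw.sum()

    records: list[tuple[str, str]] = []
    tax_rows = []
    categories: dict[str, str] = {}
    motif_sites: dict[str, int] = {}        # id -> 1-based motif start
    domain_intervals: dict[str, list[int]] = {}
    tm_decoy_ids: list[str] = []
    short_tail_ids: list[str] = []
    duplicate_groups: dict[str, list[str]] = {}

    W = len(config.motif_consensus)
    base_records: list[tuple[str, str, str, str]] = []  # id, seq, phylum, cat

    for i in range(config.n_sequences):
        sid = f"SEQ{i:05d}"
        u = rng.random()
        if u < config.frac_nonbacterial:
            cat = "nonbacterial"
        elif u < config.frac_nonbacterial + config.frac_tm_decoys:
            cat = "tm_decoy"
        elif (u < config.frac_nonbacterial + config.frac_tm_decoys
                + config.frac_short_tail):
            cat = "short_tail"
        else:
            cat = ("motif" if rng.random() < config.motif_occupancy
                   else "plain")

        domain = _noisy_copy(rng, DOMAIN_CONSENSUS[:config.domain_length],
                             config.domain_conservation)
        cterm = _sample_tail(rng, int(rng.integers(
            config.cterm_length_range[0], config.cterm_length_range[1] + 1)))
        tlo, thi = config.tail_length_range
        tail_len = int(rng.integers(tlo, thi + 1))

        if cat == "short_tail":
            tail = "M" + _sample_tail(rng, int(rng.integers(0, 7)))  # < 8
        elif cat == "tm_decoy":
            stretch = "".join(
                TM_RESIDUES[rng.integers(len(TM_RESIDUES))]
                for _ in range(int(rng.integers(19, 24))))
            pre = _sample_tail(rng, int(rng.integers(1, 5)))
            post = _sample_tail(rng, int(rng.integers(4, 10)))
            tail = "M" + pre + stretch + post
        elif cat == "motif":
            motif = _noisy_copy(rng, config.motif_consensus,
                                config.motif_conservation)
            tail = motif + _sample_tail(rng, tail_len - W)
        else:  # plain or nonbacterial: methionine start, filler tail
            tail = "M" + _sample_tail(rng, tail_len - 1)

        seq = tail + domain + cterm
        if cat == "nonbacterial":
            sk, ph = NONBACTERIAL_TAXA[int(rng.integers(
                len(NONBACTERIAL_TAXA)))]
        else:
            sk, ph = "Bacteria", phyla[int(rng.choice(len(phyla), p=pw))]
        species = f"{ph.lower()[:4]}_sp_{i:05d}"

        records.append((sid, seq))
        tax_rows.append((sid, sk, ph, species))
        categories[sid] = cat
        domain_intervals[sid] = [len(tail) + 1, len(tail) + len(domain)]
        if cat == "motif":
            motif_sites[sid] = 1
        if cat == "tm_decoy":
            tm_decoy_ids.append(sid)
        if cat == "short_tail":
            short_tail_ids.append(sid)
        if cat in ("motif", "plain"):
            base_records.append((sid, seq, ph, species))

    # within-species duplicate groups, spawned from motif/plain bases
    n_groups = min(config.n_duplicate_groups, len(base_records))
    if n_groups:
        order = rng.choice(len(base_records), size=n_groups, replace=False)
        for k, bi in enumerate(sorted(order)):
            bid, bseq, bph, bspecies = base_records[bi]
            glo, ghi = config.duplicate_group_size
            size = int(rng.integers(glo, ghi + 1))
            members = [bid]
            for d in range(size - 1):
                did = f"{bid}d{d}"
                dseq = _substitute(rng, bseq, config.duplicate_sub_rate)
                records.append((did, dseq))
                tax_rows.append((did, "Bacteria", bph, bspecies))
                categories[did] = "duplicate"
                domain_intervals[did] = domain_intervals[bid]
                members.append(did)
            duplicate_groups[bid] = members

    taxonomy = pd.DataFrame(
        tax_rows, columns=["seq_id", "superkingdom", "phylum", "species"])

    # ground-truth TM calls recomputed from the emitted tails (oracle scan)
    tm_confirmed = [sid for sid in tm_decoy_ids
                    if tm_windows(dict(records)[sid]
                                  [:domain_intervals[sid][0] - 1])]
    assert tm_confirmed == tm_decoy_ids, \
        "planted TM stretch failed the hydropathy oracle"

    ground_truth = {
        "categories": categories,
        "motif_sites": motif_sites,
        "motif_consensus": config.motif_consensus,
        "domain_intervals": domain_intervals,
        "tm_decoys": tm_decoy_ids,
        "short_tails": short_tail_ids,
        "duplicate_groups": duplicate_groups,
        "nonbacterial": [s for s, c in categories.items()
                         if c == "nonbacterial"],
    }
    return records, taxonomy, ground_truth


def generate_domain_seed_alignment(
    config: HomologSetConfig, n_members: int = 25,
) -> list[tuple[str, str]]:
    """Ungapped seed alignment of noisy domain instances, for building the
    scanning profile. Uses its own RNG stream so homolog sets are
    unaffected."""
    rng = derive_rng(config.seed, "domain_seed")
    consensus = DOMAIN_CONSENSUS[:config.domain_length]
    return [(f"seed{i:03d}",
             _noisy_copy(rng, consensus, config.domain_conservation))
            for i in range(n_members)]
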