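"""Tests of TM screening, identity/dedup, domain location and the filter
pipeline."""

import numpy as np
import pandas as pd
import pytest

import bactomts as b


# ------------------------------------------------------------ TM segments

@pytest.mark.parametrize("seq,expected", [
    ("L" * 25, [(1, 25)]),                    # uniform leucine: one segment
    ("MFSKQAKSNN" + "E" * 40, []),            # polar tail: no window passes
    ("A" * 10, []),                           # shorter than the window
])
def test_predict_tm_segments_examples(seq, expected):
    assert b.predict_tm_segments(seq) == expected


def test_tm_segment_boundaries_cover_planted_stretch():
    seq = "M" + "E" * 10 + "L" * 21 + "E" * 10
    segs = b.predict_tm_segments(seq)
    assert len(segs) == 1
    lo, hi = segs[0]
    assert lo <= 12 and hi >= 32    # full hydrophobic stretch covered


# -------------------------------------------------------- identity, dedup

@pytest.mark.parametrize("a,c,expected", [
    ("MFSKQAKS", "MFSKQAKS", 1.0),
    ("MFSK", "MFSR", 0.75),
    ("AAAA", "WWWW", 0.0),
])
def test_pairwise_identity_examples(a, c, expected):
    assert b.pairwise_identity(a, c) == pytest.approx(expected)


def test_identity_is_symmetric_and_uses_shorter_denominator():
    a, c = "MFSKQAKSTT", "MFSKQ"
    assert b.pairwise_identity(a, c) == b.pairwise_identity(c, a)
    assert b.pairwise_identity(a, c) == pytest.approx(1.0)   # 5 / 5


def _tax(rows):
    return pd.DataFrame(rows, columns=["seq_id", "superkingdom", "phylum",
                                       "species"])


def test_dedupe_is_idempotent_and_respects_species():
    base = "MFSKQAKS" + "TNGEINFYSLSTEGTGSIESNP" * 3
    near = "MFSKQAKT" + "TNGEINFYSLSTEGTGSIESNP" * 3
    records = [("A1", base), ("A2", near), ("B1", near)]
    tax = _tax([("A1", "Bacteria", "P", "sp_a"),
                ("A2", "Bacteria", "P", "sp_a"),
                ("B1", "Bacteria", "P", "sp_b")])
    kept, removal = b.dedupe(records, tax)
    assert {r[0] for r in kept} == {"A1", "B1"}   # cross-species retained
    assert removal == {"A2": "A1"}
    kept2, removal2 = b.dedupe(kept, tax)
    assert kept2 == kept and removal2 == {}


def test_dedupe_invariant_under_input_order():
    cfg = b.HomologSetConfig(n_sequences=60, seed=12, n_duplicate_groups=6)
    records, tax, truth = b.generate_homolog_set(cfg)
    kept_fwd, rem_fwd = b.dedupe(records, tax)
    kept_rev, rem_rev = b.dedupe(records[::-1], tax)
    assert {r[0] for r in kept_fwd} == {r[0] for r in kept_rev}
    assert rem_fwd == rem_rev


def test_dedupe_recovers_planted_groups():
    cfg = b.HomologSetConfig(n_sequences=80, seed=13, n_duplicate_groups=8,
                             frac_nonbacterial=0, frac_tm_decoys=0)
    records, tax, truth = b.generate_homolog_set(cfg)
    _, removal = b.dedupe(records, tax)
    expected_removed = set()
    for base, members in truth["duplicate_groups"].items():
        # equal-length members: the lexicographically smallest id is kept
        expected_removed |= set(members) - {min(members)}
    assert set(removal) == expected_removed


# --------------------------------------------------------- domain locator

def test_locate_domain_self_match_at_offset():
    core = "YRLNWARNTETNGEINFYSLSTEGTGSIESNP"
    profile = b.DomainProfile.from_seed_alignment([("s1", core)])
    seq = "A" * 20 + core + "G" * 10
    interval, score = b.locate_domain(seq, profile)
    assert interval == (21, 20 + len(core))
    assert score > 0


def test_locate_domain_recovers_planted_starts(homolog_set, domain_profile):
    cfg, records, _, truth = homolog_set
    hits = total = 0
    for sid, seq in records:
        if truth["categories"][sid] != "motif":
            continue
        total += 1
        interval, _ = b.locate_domain(seq, domain_profile)
        if interval and interval[0] == truth["domain_intervals"][sid][0]:
            hits += 1
    assert total > 50
    assert hits / total >= 0.99


def test_domain_free_sequence_rejected_by_calibrated_cutoff(
        homolog_set, domain_profile):
    """Composition-preserving null: residue-shuffled real sequences destroy
    the domain and must fall below the calibrated cutoff (the cutoff is the
    99th null percentile, so the expected false-accept rate is ~1%)."""
    _, records, _, _ = homolog_set
    rng = np.random.default_rng(42)
    rejected = 0
    n = 20
    for k in range(n):
        seq = "".join(rng.permutation(list(records[k][1])))
        interval, score = b.locate_domain(seq, domain_profile)
        if interval is None:
            rejected += 1
    assert rejected >= n - 1
    # a real domain-bearing sequence passes by a wide margin
    interval, score = b.locate_domain(records[0][1], domain_profile)
    assert interval is not None
    assert score > domain_profile.score_cutoff + 50


def test_short_sequence_flagged():
    profile = b.DomainProfile.from_seed_alignment([("s1", "ACDEFGHIKL")])
    interval, score = b.locate_domain("ACD", profile)
    assert interval is None and score == float("-inf")


# --------------------------------------------------------------- pipeline

def test_pipeline_removes_exactly_ground_truth_sets(homolog_set,
                                                    domain_profile):
    cfg, records, taxonomy, truth = homolog_set
    tails, report = b.run_filter_pipeline(records, taxonomy, domain_profile)
    assert report.telescopes()
    assert set(report.removal_ids["nonbacterial"]) == \
        set(truth["nonbacterial"])
    assert set(report.removal_ids["tm_helix"]) == set(truth["tm_decoys"])
    assert set(report.removal_ids["short_tail"]) == set(truth["short_tails"])
    expected_dupes = {m for g in truth["duplicate_groups"].values()
                      for m in set(g) - {min(g)}}
    assert set(report.removal_ids["duplicate"]) == expected_dupes
    retained = {t.seq_id for recs in tails.values() for t in recs}
    expected_retained = {sid for sid, c in truth["categories"].items()
                         if c in ("motif", "plain")} \
        | {min(g) for g in truth["duplicate_groups"].values()} \
        - expected_dupes
    assert retained == expected_retained


def test_pipeline_tails_start_with_planted_motif(homolog_set,
                                                 domain_profile):
    cfg, records, taxonomy, truth = homolog_set
    tails, _ = b.run_filter_pipeline(records, taxonomy, domain_profile)
    checked = 0
    for recs in tails.values():
        for t in recs:
            if truth["categories"][t.seq_id] != "motif":
                continue
            true_len = truth["domain_intervals"][t.seq_id][0] - 1
            assert len(t.tail) == true_len
            checked += 1
    assert checked > 50


def test_pipeline_missing_taxonomy_rejected(domain_profile, homolog_set):
    _, records, taxonomy, _ = homolog_set
    records = records[:10]
    tax = taxonomy[taxonomy["seq_id"] != records[0][0]]
    tails, report = b.run_filter_pipeline(records, tax, domain_profile)
    assert report.removed["missing_taxonomy"] == 1
    assert report.removal_ids["missing_taxonomy"] == [records[0][0]]
    assert report.telescopes()
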