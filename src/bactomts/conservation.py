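"""Bactofilin homolog filtering: TM screening, redundancy reduction, domain
location and N-terminal tail extraction.

The pipeline mirrors a standard comparative-genomics pre-processing chain:
(1) drop non-bacterial entries, (2) drop sequences whose N-terminal tail
contains a predicted transmembrane helix (these use a membrane anchor other
than the targeting peptide under study), (3) collapse >90%-identity
within-species near-duplicates, (4) locate the conserved core domain with
an ungapped log-odds profile scan, (5) drop sequences whose tails are
shorter than 8 residues. Stage counts telescope exactly.

The TM screen is a classic Kyte-Doolittle sliding-window heuristic
(window 19, threshold 1.6); the domain locator is an ungapped position-
specific scoring-matrix scan with a null-calibrated acceptance cutoff.
Both are deliberately simple, configurable stand-ins for heavier
predictors, adequate because the object of study is the tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .constants import (AA_ALPHABET, KYTE_DOOLITTLE, X_INDEX, encode_sequence,
                        scale_vector)

KD_VECTOR = np.append(scale_vector(KYTE_DOOLITTLE), 0.0)  # X -> 0


# ------------------------------------------------------------ TM screening

def predict_tm_segments(sequence: str, window: int = 19,
                        threshold: float = 1.6) -> list[tuple[int, int]]:
    """Predict transmembrane segments as maximal runs of sliding-window
    centers whose mean Kyte-Doolittle hydropathy is >= ``threshold``,
    expanded to the full window extent. Returns 1-based inclusive
    intervals; a sequence shorter than the window yields []."""
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return []
    vals = KD_VECTOR[encode_sequence(seq)]
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    hot = means >= threshold
    segments: list[tuple[int, int]] = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            segments.append((i + 1, j + window))   # 1-based, full extent
            i = j + 1
        else:
            i += 1
    return segments


# ------------------------------------------------------- pairwise identity

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions under a global alignment
    (match +1, mismatch 0, linear gap -1), divided by the length of the
    shorter sequence."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    alignment = _ALIGNER.align(a.upper(), b.upper())[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def dedupe(records: list[tuple[str, str]], taxonomy: pd.DataFrame,
           threshold: float = 0.90, within_species: bool = True,
           ) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Greedy redundancy reduction.

    Records are sorted by (length desc, id asc); each record joins the
    first retained representative (same species unless ``within_species``
    is False) with identity > ``threshold``, otherwise it becomes a
    representative. Returns retained records (input order) and a map
    removed_id -> representative_id.
    """
    species = dict(zip(taxonomy["seq_id"], taxonomy["species"]))
    order = sorted(records, key=lambda r: (-len(r[1]), r[0]))
    reps: list[tuple[str, str]] = []
    removal: dict[str, str] = {}
    for sid, seq in order:
        assigned = False
        for rid, rseq in reps:
            if within_species and species.get(sid) != species.get(rid):
                continue
            if pairwise_identity(seq, rseq) > threshold:
                removal[sid] = rid
                assigned = True
                break
        if not assigned:
            reps.append((sid, seq))
    retained_ids = {rid for rid, _ in reps}
    return [r for r in records if r[0] in retained_ids], removal


# ----------------------------------------------------------- domain scans

@dataclass
class DomainProfile:
    """Ungapped position-specific log-odds profile over the 20 letters.

    Built from an ungapped seed alignment with per-cell pseudocounts;
    the background is the pooled seed composition. ``score_cutoff`` (if
    set) is the acceptance threshold below which a scanned sequence is
    flagged as domain-free.
    """

    log_odds: np.ndarray                  # (L, 21); X column = 0
    background: np.ndarray                # (20,)
    score_cutoff: float | None = None

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @classmethod
    def from_seed_alignment(cls, alignment: list[tuple[str, str]],
                            pseudocount: float = 0.5) -> "DomainProfile":
        seqs = [s.upper() for _, s in alignment]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("seed alignment members must have equal length")
        enc = np.array([encode_sequence(s) for s in seqs])
        L = enc.shape[1]
        counts = np.zeros((L, 20))
        for a in range(20):
            counts[:, a] = (enc == a).sum(axis=0)
        freqs = counts + pseudocount
        freqs /= freqs.sum(axis=1, keepdims=True)
        bg = counts.sum(axis=0) + pseudocount
        bg /= bg.sum()
        lo = np.zeros((L, 21))
        lo[:, :20] = np.log2(freqs / bg)
        return cls(log_odds=lo, background=bg)

    def window_scores(self, sequence: str) -> np.ndarray:
        """Log-odds score of every window (empty if sequence too short)."""
        enc = encode_sequence(sequence.upper())
        n, L = len(enc), self.length
        if n < L:
            return np.array([])
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = np.zeros(windows.shape[0])
        for col in range(L):
            scores += self.log_odds[col, windows[:, col]]
        return scores

    def calibrate_cutoff(self, sequences: list[str], rng: np.random.Generator,
                         n_shuffles: int = 200,
                         percentile: float = 99.0) -> float:
        """Set the acceptance cutoff to the given percentile of max-window
        scores over residue-shuffled versions of the supplied sequences."""
        maxima = []
        seqs = [s for s in sequences if len(s) >= self.length]
        if not seqs:
            raise ValueError("no sequence long enough to calibrate on")
        for k in range(n_shuffles):
            s = seqs[k % len(seqs)]
            shuffled = "".join(rng.permutation(list(s)))
            maxima.append(self.window_scores(shuffled).max())
        self.score_cutoff = float(np.percentile(maxima, percentile))
        return self.score_cutoff


def locate_domain(sequence: str, profile: DomainProfile,
                  ) -> tuple[tuple[int, int] | None, float]:
    """Best-scoring ungapped placement of the profile (1-based inclusive
    interval) and its log-odds score. Ties break to the smallest start.
    Returns (None, -inf) for sequences shorter than the profile and
    (None, score) when a calibrated cutoff rejects the best window."""
    scores = profile.window_scores(sequence)
    if scores.size == 0:
        return None, float("-inf")
    start = int(np.argmax(scores))          # argmax takes the first maximum
    score = float(scores[start])
    if profile.score_cutoff is not None and score < profile.score_cutoff:
        return None, score
    return (start + 1, start + profile.length), score


# --------------------------------------------------------------- pipeline

@dataclass
class TailRecord:
    seq_id: str
    tail: str
    domain_interval: tuple[int, int]
    phylum: str


@dataclass
class PipelineReport:
    n_input: int
    removed: dict[str, int]
    removal_ids: dict[str, list[str]]
    duplicate_map: dict[str, str]
    n_retained: int
    per_phylum: dict[str, int] = field(default_factory=dict)

    def telescopes(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input, "removed": self.removed,
            "removal_ids": self.removal_ids,
            "duplicate_map": self.duplicate_map,
            "n_retained": self.n_retained, "per_phylum": self.per_phylum,
        }


STAGES = ("missing_taxonomy", "nonbacterial", "tm_helix", "duplicate",
          "no_domain", "short_tail")


def run_filter_pipeline(records: list[tuple[str, str]],
                        taxonomy: pd.DataFrame, profile: DomainProfile,
                        min_tail: int = 8, identity_threshold: float = 0.90,
                        tm_window: int = 19, tm_threshold: float = 1.6,
                        within_species: bool = True,
                        ) -> tuple[dict[str, list[TailRecord]],
                                   PipelineReport]:
    """Apply the filtering stages in order and extract per-phylum tails.

    TM removal triggers only when a predicted segment overlaps the region
    N-terminal of the located domain (an N-terminal membrane anchor); a
    sequence whose best domain placement is rejected by the profile cutoff
    is removed at the ``no_domain`` stage.
    """
    tax = taxonomy.set_index("seq_id")
    removed: dict[str, int] = {s: 0 for s in STAGES}
    removal_ids: dict[str, list[str]] = {s: [] for s in STAGES}

    # pre-compute domain placement once per record
    placements: dict[str, tuple[tuple[int, int] | None, float]] = {
        sid: locate_domain(seq, profile) for sid, seq in records}

    survivors: list[tuple[str, str]] = []
    for sid, seq in records:
        if sid not in tax.index:
            removed["missing_taxonomy"] += 1
            removal_ids["missing_taxonomy"].append(sid)
            continue
        survivors.append((sid, seq))

    stage2 = []
    for sid, seq in survivors:
        if tax.loc[sid, "superkingdom"] != "Bacteria":
            removed["nonbacterial"] += 1
            removal_ids["nonbacterial"].append(sid)
        else:
            stage2.append((sid, seq))

    stage3 = []
    for sid, seq in stage2:
        interval, _ = placements[sid]
        domain_start = interval[0] if interval else len(seq) + 1
        segments = predict_tm_segments(seq, tm_window, tm_threshold)
        n_terminal_tm = any(s[0] < domain_start for s in segments)
        if n_terminal_tm:
            removed["tm_helix"] += 1
            removal_ids["tm_helix"].append(sid)
        else:
            stage3.append((sid, seq))

    stage4, duplicate_map = dedupe(stage3, taxonomy, identity_threshold,
                                   within_species)
    removed["duplicate"] = len(duplicate_map)
    removal_ids["duplicate"] = sorted(duplicate_map)

    tails: dict[str, list[TailRecord]] = {}
    n_retained = 0
    for sid, seq in stage4:
        interval, _ = placements[sid]
        if interval is None:
            removed["no_domain"] += 1
            removal_ids["no_domain"].append(sid)
            continue
        tail = seq[: interval[0] - 1]
        if len(tail) < min_tail:
            removed["short_tail"] += 1
            removal_ids["short_tail"].append(sid)
            continue
        phylum = str(tax.loc[sid, "phylum"])
        tails.setdefault(phylum, []).append(
            TailRecord(sid, tail, interval, phylum))
        n_retained += 1

    report = PipelineReport(
        n_input=len(records), removed=removed, removal_ids=removal_ids,
        duplicate_map=duplicate_map, n_retained=n_retained,
        per_phylum={p: len(v) for p, v in sorted(tails.items())})
    assert report.telescopes(), "pipeline stage counts failed to telescope"
    return tails, report
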