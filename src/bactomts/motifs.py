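"""ZOOPS expectation-maximization motif discovery over N-terminal tails.

Model
-----
Each sequence contains zero or one occurrence of an ungapped motif of width
W ("ZOOPS"). With per-sequence occupancy prior lambda and a uniform site
prior over the m = L - W + 1 possible starts, the likelihood of sequence S
is

    P(S) = (1 - lambda) P0(S) + (lambda / m) sum_j Pj(S)

where P0 scores every position under a fixed 0th-order background (pooled
tail composition) and Pj scores the window starting at j under the
position-weight matrix (PWM) and the rest under the background. EM
alternates site-posterior computation (E) with pseudocounted PWM and
lambda re-estimation (M); the log-likelihood is non-decreasing at every
iteration and the run aborts if it ever drops beyond round-off.

Width selection maximizes the log-likelihood ratio over pure background
penalized by a minimum per-site information contribution per column (see
``width_objective``); successive motifs are found after hard-erasing
(masking to X) the sites the previous motif claims with posterior > 0.5.
The letter X is ignored wherever it occurs: it contributes probability 1
to any PWM column and to the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AA_ALPHABET, X_INDEX, encode_sequence

LOG2_20 = np.log2(20.0)


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray                       # (W, 20), rows sum to 1
    background: np.ndarray                # (20,)
    occupancy: float                      # lambda
    log_likelihood: float
    llr: float                            # ll minus pure-background ll, nats
    site_posteriors: list[np.ndarray]     # per sequence, (m_i,) start probs
    presence_posterior: np.ndarray        # (n_seqs,)
    ll_trace: list[float] = field(default_factory=list)
    n_sequences_used: int = 0
    n_sequences_skipped: int = 0

    @property
    def consensus(self) -> str:
        return consensus(self)

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits: log2(20) - H(column)."""
        p = np.clip(self.pwm, 1e-300, 1.0)
        return LOG2_20 + (p * np.log2(p)).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "width": self.width, "consensus": self.consensus,
            "occupancy": self.occupancy,
            "log_likelihood": self.log_likelihood,
            "llr": self.llr,
            "pwm": self.pwm.tolist(), "background": self.background.tolist(),
            "alphabet": AA_ALPHABET,
            "information_content": self.information_content().tolist(),
            "n_sequences_used": self.n_sequences_used,
            "n_sequences_skipped": self.n_sequences_skipped,
        }


def consensus(motif: MotifModel) -> str:
    """Per-column argmax letter; ties break alphabetically (argmax returns
    the first maximum and the alphabet is stored alphabetically)."""
    return "".join(AA_ALPHABET[i] for i in motif.pwm.argmax(axis=1))


def build_logo(motif: MotifModel) -> np.ndarray:
    """Logo letter heights, (W, 20): height(i, a) = p(i, a) * IC(i) with
    IC in bits and no small-sample correction."""
    return motif.pwm * motif.information_content()[:, None]


def background_from_tails(tails: list[str]) -> np.ndarray:
    """Pooled 0th-order residue composition of the tails (X excluded),
    with a small floor so every letter has positive probability."""
    counts = np.zeros(20)
    for t in tails:
        enc = encode_sequence(t)
        enc = enc[enc != X_INDEX]
        counts += np.bincount(enc, minlength=20)
    counts += 0.01
    return counts / counts.sum()


# ----------------------------------------------------------------- EM core

class _WidthData:
    """Stacked windows of every usable tail at one width."""

    def __init__(self, tails: list[str], width: int):
        self.width = width
        encs = [encode_sequence(t) for t in tails]
        self.used = [i for i, e in enumerate(encs) if len(e) >= width]
        self.skipped = len(tails) - len(self.used)
        windows = []
        seq_of_window = []
        self.m = []                       # windows per used sequence
        self.full_counts = np.zeros(21)
        for k, i in enumerate(self.used):
            e = encs[i]
            w = np.lib.stride_tricks.sliding_window_view(e, width)
            windows.append(w)
            seq_of_window.append(np.full(w.shape[0], k))
            self.m.append(w.shape[0])
            self.full_counts += np.bincount(e, minlength=21)
        self.windows = np.vstack(windows) if windows else \
            np.empty((0, width), dtype=np.int64)
        self.seq_of_window = np.concatenate(seq_of_window) if windows else \
            np.empty(0, dtype=np.int64)
        self.m = np.array(self.m)
        self.offsets = np.concatenate([[0], np.cumsum(self.m)])
        self.n_seqs = len(self.used)

    def window_log_ratio(self, log_pwm_over_bg: np.ndarray) -> np.ndarray:
        """Sum over columns of log(PWM/bg) for every window; X columns
        contribute 0 (the padded 21st row of the ratio matrix)."""
        s = np.zeros(self.windows.shape[0])
        for col in range(self.width):
            s += log_pwm_over_bg[col, self.windows[:, col]]
        return s


def _log_background_total(data: _WidthData, log_bg: np.ndarray) -> float:
    """Sum of log background probability of every residue of every used
    sequence (X contributes 0)."""
    lb = np.append(log_bg, 0.0)
    return float((data.full_counts * lb).sum())


def _em_run(data: _WidthData, background: np.ndarray, pwm0: np.ndarray,
            lambda0: float, tol: float, max_iter: int, pseudocount: float,
            ) -> tuple[np.ndarray, float, float, np.ndarray, np.ndarray,
                       list[float]]:
    """One EM run from a given initialization. Returns (pwm, lambda,
    data log-likelihood, window posteriors, presence posteriors,
    objective trace).

    With pseudocounts the M-step is the MAP update under a Dirichlet(1 +
    pseudocount) prior on every PWM column, so the quantity EM maximizes
    monotonically is the penalized objective ll + pseudocount * sum(log
    pwm); that objective is what the trace records and what the
    monotonicity guard checks.
    """
    log_bg = np.log(background)
    const_ll = _log_background_total(data, log_bg)
    pwm = pwm0.copy()
    lam = float(lambda0)
    trace: list[float] = []
    post = np.zeros(data.windows.shape[0])
    presence = np.zeros(data.n_seqs)
    prev_obj = -np.inf
    ll = const_ll
    for it in range(max_iter):
        # E-step ----------------------------------------------------------
        log_pwm = np.log(np.clip(pwm, 1e-300, None))
        lr = np.zeros((data.width, 21))
        lr[:, :20] = log_pwm - log_bg
        s = data.window_log_ratio(lr)
        if lam <= 0.0:
            post[:] = 0.0
            presence[:] = 0.0
            ll = const_ll
        else:
            # per sequence: mix = (1-lam) + (lam/m) sum_j exp(s_j)
            smax = np.maximum.reduceat(s, data.offsets[:-1])
            es = np.exp(s - smax[data.seq_of_window])
            sums = np.add.reduceat(es, data.offsets[:-1])
            log_site_term = np.log(lam / data.m) + smax + np.log(sums)
            log_nosite = np.log1p(-lam) if lam < 1.0 else -np.inf
            mx = np.maximum(log_site_term, log_nosite)
            log_mix = mx + np.log(np.exp(log_site_term - mx)
                                  + np.exp(log_nosite - mx))
            presence = np.exp(log_site_term - log_mix)
            post = es / sums[data.seq_of_window] \
                * presence[data.seq_of_window]
            ll = const_ll + float(log_mix.sum())
        obj = ll + pseudocount * float(log_pwm.sum())
        trace.append(obj)
        if obj < prev_obj - 1e-8 * max(1.0, abs(prev_obj)):
            raise RuntimeError(
                f"EM objective decreased at iteration {it}: "
                f"{prev_obj} -> {obj}")
        if prev_obj > -np.inf and abs(obj - prev_obj) <= tol * abs(prev_obj):
            break
        prev_obj = obj
        # M-step ----------------------------------------------------------
        counts = np.zeros((data.width, 21))
        for col in range(data.width):
            np.add.at(counts[col], data.windows[:, col], post)
        c20 = counts[:, :20] + pseudocount
        pwm = c20 / c20.sum(axis=1, keepdims=True)
        lam = float(presence.mean()) if data.n_seqs else 0.0
        lam = min(max(lam, 0.0), 1.0)
    return pwm, lam, ll, post, presence, trace


def _seed_pwms(data: _WidthData, restarts: int,
               seed_weight: float = 0.7) -> list[np.ndarray]:
    """Initial PWMs from the most frequent exact substrings of this width
    (MEME-style subsequence seeding)."""
    from collections import Counter
    counter: Counter = Counter(map(tuple, data.windows.tolist()))
    seeds = [w for w, _ in counter.most_common(restarts)]
    pwms = []
    other = (1.0 - seed_weight) / 19.0
    for s in seeds:
        pwm = np.full((data.width, 20), other)
        for col, letter in enumerate(s):
            if letter < 20:
                pwm[col] = other
                pwm[col, letter] = seed_weight
            else:                           # X in the seed: uniform column
                pwm[col] = 1.0 / 20.0
        pwms.append(pwm)
    return pwms


def fit_zoops(tails: list[str], width: int, background: np.ndarray,
              restarts: int = 20, tol: float = 1e-6, max_iter: int = 200,
              pseudocount: float = 0.01, lambda_init: float = 0.5,
              ) -> MotifModel | None:
    """Best-of-``restarts`` ZOOPS EM fit at a fixed width. Returns None
    when no tail is long enough."""
    data = _WidthData(tails, width)
    if data.n_seqs < 2:
        return None
    best = None
    for pwm0 in _seed_pwms(data, restarts):
        pwm, lam, ll, post, presence, trace = _em_run(
            data, background, pwm0, lambda_init, tol, max_iter, pseudocount)
        if best is None or ll > best[2]:
            best = (pwm, lam, ll, post, presence, trace)
    pwm, lam, ll, post, presence, trace = best
    const_ll = _log_background_total(data, np.log(background))
    site_posteriors = [post[data.offsets[k]: data.offsets[k + 1]]
                       for k in range(data.n_seqs)]
    # expand to the original tail indexing (skipped tails -> empty)
    expanded: list[np.ndarray] = [np.array([]) for _ in tails]
    pres_full = np.zeros(len(tails))
    for k, i in enumerate(data.used):
        expanded[i] = site_posteriors[k]
        pres_full[i] = presence[k]
    return MotifModel(width=width, pwm=pwm, background=background,
                      occupancy=lam, log_likelihood=ll,
                      llr=ll - const_ll,
                      site_posteriors=expanded,
                      presence_posterior=pres_full, ll_trace=trace,
                      n_sequences_used=data.n_seqs,
                      n_sequences_skipped=data.skipped)


def width_objective(motif: MotifModel,
                    column_penalty: float = 1.0) -> float:
    """Width-selection objective, the package's stand-in for a motif
    E-value: the log-likelihood ratio of the motif model over pure
    background, minus ``column_penalty`` bits of relative entropy per
    expected site for every column (default: one bit per site),

        obj = LLR_nats - column_penalty * ln2 * (lambda * n_used) * W.

    Every column must carry at least ``column_penalty`` bits of per-site
    information against the background to pay for itself, so widths are
    not inflated by weak compositional bias flanking a sharp motif."""
    sites = motif.occupancy * motif.n_sequences_used
    return float(motif.llr
                 - column_penalty * np.log(2.0) * sites * motif.width)


def _mask_sites(tails: list[str], motif: MotifModel,
                threshold: float = 0.5) -> list[str]:
    """Hard-erase (mask to X) the window of each sequence whose best site
    posterior exceeds ``threshold``."""
    out = []
    for t, post in zip(tails, motif.site_posteriors):
        if post.size and post.max() > threshold:
            j = int(post.argmax())
            t = t[:j] + "X" * motif.width + t[j + motif.width:]
        out.append(t)
    return out


def discover_motifs(tails: list[str], n_motifs: int = 10, w_min: int = 5,
                    w_max: int = 50, restarts: int = 20, tol: float = 1e-6,
                    column_penalty: float = 1.0, seed: int = 0,
                    ) -> list[MotifModel]:
    """Discover up to ``n_motifs`` motifs by repeated ZOOPS EM.

    For every width in [w_min, w_max] the best of ``restarts`` seeded EM
    runs is kept; the width maximizing ``width_objective`` wins (ties to
    the smaller width). Sites of each reported motif are erased before the
    next round. ``seed`` is accepted for interface stability; the seeded
    initializations themselves are deterministic.
    """
    if len(tails) < 2:
        raise ValueError("need at least 2 tails")
    if any(len(t) < w_min for t in tails):
        raise ValueError(f"every tail must be at least w_min={w_min} long")
    background = background_from_tails(tails)
    current = list(tails)
    found: list[MotifModel] = []
    for _ in range(n_motifs):
        best: MotifModel | None = None
        best_obj = -np.inf
        for width in range(w_min, w_max + 1):
            model = fit_zoops(current, width, background, restarts, tol)
            if model is None:
                continue
            obj = width_objective(model, column_penalty)
            if obj > best_obj + 1e-12:
                best, best_obj = model, obj
        if best is None:
            break
        found.append(best)
        current = _mask_sites(current, best)
    return found


# ---------------------------------------------------------- oracle helpers

def zoops_hard_assignment_ll(tails: list[str], width: int,
                             assignment: list[int | None],
                             background: np.ndarray,
                             pseudocount: float = 0.01) -> float:
    """ZOOPS log-likelihood of a hard site assignment with parameters set
    to the assignment-derived MLEs (brute-force oracle used in tests).

    ``assignment[i]`` is the 0-based motif start in tail i, or None.
    """
    n_with = sum(a is not None for a in assignment)
    lam = n_with / len(tails)
    counts = np.zeros((width, 20))
    for t, a in zip(tails, assignment):
        if a is None:
            continue
        enc = encode_sequence(t[a:a + width])
        for col, letter in enumerate(enc):
            if letter < 20:
                counts[col, letter] += 1
    pwm = counts + pseudocount
    pwm /= pwm.sum(axis=1, keepdims=True)
    data = _WidthData(tails, width)
    log_bg = np.log(background)
    const_ll = _log_background_total(data, log_bg)
    lr = np.zeros((width, 21))
    lr[:, :20] = np.log(pwm) - log_bg
    s = data.window_log_ratio(lr)
    total = const_ll
    for k in range(data.n_seqs):
        sk = s[data.offsets[k]: data.offsets[k + 1]]
        m = data.m[k]
        mix = (1 - lam) + (lam / m) * np.exp(sk).sum()
        total += np.log(mix)
    return float(total)
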