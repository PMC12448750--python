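"""Tests of ZOOPS-EM motif discovery, consensus and logos."""

import itertools

import numpy as np
import pytest

import bactomts as b
from bactomts.motifs import (MotifModel, background_from_tails, fit_zoops,
                             width_objective, zoops_hard_assignment_ll)
from bactomts.synthetic_sequences import _sample_tail

LOG2_20 = np.log2(20.0)


def _model_from_pwm(pwm):
    return MotifModel(width=pwm.shape[0], pwm=pwm,
                      background=np.full(20, 0.05), occupancy=1.0,
                      log_likelihood=0.0, llr=0.0, site_posteriors=[],
                      presence_posterior=np.array([]))


# ----------------------------------------------------- consensus and logo

def test_consensus_unit_columns_and_tie_break():
    pwm = np.zeros((3, 20))
    pwm[0, 10] = 1.0          # M
    pwm[1, 4] = 1.0           # F
    pwm[2, :] = 1.0 / 20.0    # uniform: alphabetical tie-break -> A
    m = _model_from_pwm(pwm)
    assert m.consensus == "MFA"


def test_consensus_survives_pseudocounting():
    from bactomts.constants import AA_INDEX
    tails = ["MFSKQAKS"] * 100
    bg = background_from_tails(tails)
    model = fit_zoops(tails, 8, bg, restarts=3)
    assert model.consensus == "MFSKQAKS"


@pytest.mark.parametrize("column,expected_heights", [
    # deterministic column: single letter at full information
    (np.eye(20)[0], {0: LOG2_20}),
    # uniform column: all heights zero
    (np.full(20, 0.05), {}),
    # two-letter column: IC = log2(20) - 1, split equally
    (np.array([0.5, 0.5] + [0.0] * 18),
     {0: (LOG2_20 - 1) / 2, 1: (LOG2_20 - 1) / 2}),
])
def test_logo_heights(column, expected_heights):
    pwm = column[None, :]
    heights = b.build_logo(_model_from_pwm(pwm))[0]
    for idx, h in expected_heights.items():
        assert heights[idx] == pytest.approx(h, abs=1e-12)
    others = [i for i in range(20) if i not in expected_heights]
    assert np.allclose(heights[others], 0.0, atol=1e-12)


# ------------------------------------------------------------------- EM

def test_shared_prefix_dominates_and_lambda_goes_to_one():
    rng = np.random.default_rng(0)
    tails = ["MFSKQAKS" + _sample_tail(rng, 12) for _ in range(40)]
    bg = background_from_tails(tails)
    model = fit_zoops(tails, 8, bg)
    assert model.consensus == "MFSKQAKS"
    assert model.occupancy > 0.95
    # the claimed site is the prefix in every sequence
    for post in model.site_posteriors:
        assert post.argmax() == 0


def test_em_objective_monotone_within_run():
    rng = np.random.default_rng(1)
    tails = ["MFSKKKK" + _sample_tail(rng, 15) for _ in range(30)]
    bg = background_from_tails(tails)
    model = fit_zoops(tails, 7, bg)
    trace = np.array(model.ll_trace)
    assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))


def test_lambda_zero_reduces_to_pure_background():
    tails = ["MFSKQAKSNN", "MFSKQAKSEE", "MFSKQAKSTT"]
    bg = background_from_tails(tails)
    model = fit_zoops(tails, 5, bg, lambda_init=0.0)
    assert model.occupancy == 0.0
    expected = sum(np.log(bg[i]) for t in tails
                   for i in map("ACDEFGHIKLMNPQRSTVWY".index, t))
    assert model.log_likelihood == pytest.approx(expected)


def test_em_beats_every_hard_assignment_on_tiny_instance():
    """Brute-force oracle: the EM mixture optimum's likelihood must be at
    least that of every exhaustive hard site assignment evaluated at its
    own MLE parameters."""
    rng = np.random.default_rng(2)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    width = 5
    tails = ["MFSKK" + "".join(rng.choice(letters, size=5))
             for _ in range(4)]
    bg = background_from_tails(tails)
    model = fit_zoops(tails, width, bg, restarts=30)
    options = [range(-1, len(t) - width + 1) for t in tails]
    best_hard = -np.inf
    for combo in itertools.product(*options):
        assignment = [None if c < 0 else c for c in combo]
        best_hard = max(best_hard, zoops_hard_assignment_ll(
            tails, width, assignment, bg))
    assert model.log_likelihood >= best_hard - 1e-6 * abs(best_hard)


def test_x_letters_are_ignored():
    tails = ["MFSKQXKS" + "EEEEEEEE" for _ in range(20)]
    bg = background_from_tails(tails)
    model = fit_zoops(tails, 8, bg)
    assert model.consensus[:5] == "MFSKQ"
    assert model.consensus[6:] == "KS"


def test_discover_motifs_masks_first_motif_before_second():
    rng = np.random.default_rng(3)
    tails = ["MFSKKKK" + _sample_tail(rng, 13) for _ in range(60)]
    models = b.discover_motifs(tails, n_motifs=2, w_min=5, w_max=9,
                               restarts=10)
    assert models[0].consensus == "MFSKKKK"
    if len(models) > 1:
        assert models[1].consensus != models[0].consensus


def test_discover_motifs_input_validation():
    with pytest.raises(ValueError):
        b.discover_motifs(["MFSKKKK"])
    with pytest.raises(ValueError):
        b.discover_motifs(["MFS", "MFSKKKKAAAA"], w_min=5)


def test_width_objective_prefers_true_width():
    rng = np.random.default_rng(4)
    tails = ["MFSKKKK" + _sample_tail(rng, 13) for _ in range(80)]
    bg = background_from_tails(tails)
    objs = {w: width_objective(fit_zoops(tails, w, bg, restarts=10))
            for w in (5, 6, 7, 8, 9)}
    assert max(objs, key=objs.get) == 7
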