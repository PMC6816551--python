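import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirrormix import (
    CorrectOrGuessParams,
    ExpDecayParams,
    Hierarchy,
    SMCParams,
    cog_weights,
    dataset_nll,
    exp_weights,
    make_model,
    sample_response,
    smc_weights,
    structured_weights,
)
from mirrormix.layouts import canonical_layout

from conftest import random_trials

probs = st.floats(0.0, 1.0)


# ---------------------------------------------------------------------------
# component weights
# ---------------------------------------------------------------------------


def test_smc_delta_case(arctic):
    w = smc_weights(SMCParams(p1=1, p2=1, p3=1, sigma=0.1), arctic, 3)
    assert w[arctic.target_index(3)] == 1.0
    assert w.sum() == pytest.approx(1.0)


def test_smc_uniform_at_half(arctic):
    w = smc_weights(SMCParams(p1=0.5, p2=0.5, p3=0.5, sigma=0.1), arctic, 0)
    assert np.allclose(w, 1 / 8)


def test_smc_published_mirror_weight(arctic):
    # fitted stage probabilities of the youngest group give a 24% mirror rate
    w = smc_weights(SMCParams(p1=0.79, p2=0.77, p3=0.61, sigma=0.1), arctic, 5)
    mirror = arctic.target_index(arctic.mirror_of(5))
    assert w[mirror] == pytest.approx(0.79 * 0.77 * 0.39, abs=1e-12)
    assert round(100 * w[mirror]) == 24


def test_smc_jetty_drops_p2(jetty):
    w = smc_weights(SMCParams(p1=0.9, p3=0.7, sigma=0.1), jetty, 0)
    assert w[jetty.target_index(0)] == pytest.approx(0.9 * 0.7)
    assert w[jetty.target_index(jetty.mirror_of(0))] == pytest.approx(0.9 * 0.3)
    others = [i for i, t in enumerate(jetty.targets) if t.landmark_id != 0]
    assert np.allclose(w[others], 0.1 / 4)


def test_cog_published_wrong_target_weight(arctic):
    w = cog_weights(CorrectOrGuessParams(pc=0.46, sigma=0.1), arctic, 5)
    wrong = [i for i in range(8) if i != arctic.target_index(5)]
    assert np.allclose(w[wrong], 0.54 / 7)
    assert round(100 * w[wrong[0]]) == 8


def test_cog_uniform_at_one_over_T(arctic):
    w = cog_weights(CorrectOrGuessParams(pc=1 / 8, sigma=0.1), arctic, 2)
    assert np.allclose(w, 1 / 8)


def test_exp_weights_limits(arctic):
    w0 = exp_weights(ExpDecayParams(k=0.0, sigma=0.1), arctic, 4)
    assert np.allclose(w0, 1 / 8)
    wbig = exp_weights(ExpDecayParams(k=200.0, sigma=0.1), arctic, 4)
    assert wbig[arctic.target_index(4)] == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("k", [0.058, 0.5, 2.0])
def test_exp_correct_target_has_largest_weight(arctic, k):
    for t in arctic.target_ids:
        w = exp_weights(ExpDecayParams(k=k, sigma=0.1), arctic, t)
        assert w.argmax() == arctic.target_index(t)


def test_structured_matches_smc_on_canonical_hierarchy(arctic):
    h = Hierarchy.single_multi_cue(arctic)
    for t in arctic.target_ids:
        ws = structured_weights(h, 0.79, 0.77, 0.61, arctic, t)
        wm = smc_weights(SMCParams(p1=0.79, p2=0.77, p3=0.61, sigma=0.1), arctic, t)
        assert np.allclose(ws, wm)


def test_structured_delta_and_uniform(arctic):
    h = Hierarchy.single_multi_cue(arctic)
    w = structured_weights(h, 1, 1, 1, arctic, 6)
    assert w[arctic.target_index(6)] == 1.0
    w = structured_weights(h, 0.5, 0.5, 0.5, arctic, 6)
    assert np.allclose(w, 1 / 8)


def test_unknown_target_errors(arctic):
    with pytest.raises(KeyError):
        smc_weights(SMCParams(p1=0.5, p2=0.5, p3=0.5, sigma=0.1), arctic, 99)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(p1=probs, p2=probs, p3=probs, pc=probs,
       k=st.floats(0.0, 10.0), tid=st.integers(0, 7))
def test_all_weight_vectors_are_distributions(p1, p2, p3, pc, k, tid):
    arctic = canonical_layout("arctic")
    jetty = canonical_layout("jetty")
    h = Hierarchy.single_multi_cue(arctic)
    vectors = [
        smc_weights(SMCParams(p1=p1, p2=p2, p3=p3, sigma=0.1), arctic, tid),
        cog_weights(CorrectOrGuessParams(pc=pc, sigma=0.1), arctic, tid),
        exp_weights(ExpDecayParams(k=k, sigma=0.1), arctic, tid),
        structured_weights(h, p1, p2, p3, arctic, tid),
        smc_weights(SMCParams(p1=p1, p3=p3, sigma=0.1), jetty, tid % 6),
        cog_weights(CorrectOrGuessParams(pc=pc, sigma=0.1), jetty, tid % 6),
        exp_weights(ExpDecayParams(k=k, sigma=0.1), jetty, tid % 6),
    ]
    for w in vectors:
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_hierarchy_canonical_equality():
    a = Hierarchy.from_pairs(((0, 1), (2, 3)), ((4, 5), (6, 7)))
    b = Hierarchy.from_pairs(((7, 6), (5, 4)), ((3, 2), (1, 0)))
    assert a == b
    with pytest.raises(ValueError):
        Hierarchy.from_pairs(((0, 1), (2, 3)), ((4, 5), (6, 6)))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_nll_closed_form_single_trial(arctic):
    # delta weights on the trial's own target, response at that centre:
    # density is the single Gaussian's peak 1/(2 pi sigma^2)
    sigma = 0.3
    t = arctic.targets[2]
    trials = pd.DataFrame({"target_id": [t.id],
                           "response_x_m": [t.position[0]],
                           "response_y_m": [t.position[1]]})
    nll = dataset_nll("smc", SMCParams(p1=1, p2=1, p3=1, sigma=sigma),
                      arctic, trials)
    assert nll == pytest.approx(math.log(2 * math.pi * sigma ** 2), abs=1e-12)


def test_nll_additive_over_splits(arctic):
    rng = np.random.default_rng(0)
    trials = random_trials(arctic, 40, rng)
    p = CorrectOrGuessParams(pc=0.7, sigma=0.2)
    whole = dataset_nll("cog", p, arctic, trials)
    a = dataset_nll("cog", p, arctic, trials.iloc[:17])
    b = dataset_nll("cog", p, arctic, trials.iloc[17:])
    assert whole == pytest.approx(a + b, rel=1e-12)


def brute_force_nll(weight_fn, layout, trials, sigma):
    """Independent oracle: direct per-component density summation."""
    total = 0.0
    for _, tr in trials.iterrows():
        w = weight_fn(int(tr["target_id"]))
        dens = 0.0
        for j, tgt in enumerate(layout.targets):
            d2 = ((tr["response_x_m"] - tgt.position[0]) ** 2
                  + (tr["response_y_m"] - tgt.position[1]) ** 2)
            dens += w[j] * math.exp(-d2 / (2 * sigma ** 2)) / (2 * math.pi * sigma ** 2)
        total -= math.log(dens)
    return total


@pytest.mark.parametrize("family,params", [
    ("smc", SMCParams(p1=0.7, p2=0.6, p3=0.55, sigma=0.22)),
    ("cog", CorrectOrGuessParams(pc=0.4, sigma=0.3)),
    ("exp", ExpDecayParams(k=1.3, sigma=0.18)),
])
def test_nll_matches_bruteforce(arctic, family, params):
    from mirrormix.response_models import weights_for

    rng = np.random.default_rng(42)
    trials = random_trials(arctic, 25, rng)
    expected = brute_force_nll(
        lambda t: weights_for(family, params, arctic, t), arctic, trials,
        params.sigma)
    got = dataset_nll(family, params, arctic, trials)
    assert got == pytest.approx(expected, abs=1e-10)


def test_uniform_equivalence_of_families(arctic):
    rng = np.random.default_rng(1)
    trials = random_trials(arctic, 30, rng)
    n_smc = dataset_nll("smc", SMCParams(p1=0.5, p2=0.5, p3=0.5, sigma=0.25),
                        arctic, trials)
    n_cog = dataset_nll("cog", CorrectOrGuessParams(pc=1 / 8, sigma=0.25),
                        arctic, trials)
    n_exp = dataset_nll("exp", ExpDecayParams(k=0.0, sigma=0.25), arctic, trials)
    assert n_smc == pytest.approx(n_cog, rel=1e-12)
    assert n_smc == pytest.approx(n_exp, rel=1e-12)


def test_empty_trials_error(arctic):
    with pytest.raises(ValueError):
        dataset_nll("cog", CorrectOrGuessParams(pc=0.5, sigma=0.1),
                    arctic, pd.DataFrame(columns=["target_id", "response_x_m",
                                                  "response_y_m"]))


def test_trials_with_unknown_target_error(arctic):
    trials = pd.DataFrame({"target_id": [55], "response_x_m": [0.0],
                           "response_y_m": [0.0]})
    with pytest.raises(ValueError, match="unknown target"):
        dataset_nll("cog", CorrectOrGuessParams(pc=0.5, sigma=0.1), arctic, trials)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def test_sample_response_deterministic(arctic):
    p = SMCParams(p1=0.8, p2=0.7, p3=0.6, sigma=0.2)
    a = [sample_response("smc", p, arctic, 1, np.random.default_rng(9))
         for _ in range(5)]
    b = [sample_response("smc", p, arctic, 1, np.random.default_rng(9))
         for _ in range(5)]
    assert np.allclose(a, b)


def test_sample_response_tiny_sigma_lands_on_centres(arctic):
    p = CorrectOrGuessParams(pc=0.5, sigma=1e-9)
    pos = arctic.target_positions()
    rng = np.random.default_rng(2)
    for _ in range(20):
        r = sample_response("cog", p, arctic, 3, rng)
        assert np.min(np.linalg.norm(pos - r, axis=1)) < 1e-6


def test_sample_component_frequencies_match_weights(arctic):
    p = CorrectOrGuessParams(pc=1 / 3, sigma=0.02)
    w = cog_weights(p, arctic, 0)
    rng = np.random.default_rng(4)
    n = 10_000
    pos = arctic.target_positions()
    counts = np.zeros(8)
    for _ in range(n):
        r = sample_response("cog", p, arctic, 0, rng)
        counts[np.linalg.norm(pos - r, axis=1).argmin()] += 1
    freq = counts / n
    se = np.sqrt(w * (1 - w) / n)
    assert (np.abs(freq - w) <= 4 * se).all()


# ---------------------------------------------------------------------------
# fit results object
# ---------------------------------------------------------------------------


def test_fit_results_summary_and_weights(arctic, smc_trials_small):
    model = make_model("smc", smc_trials_small, arctic)
    res = model.fit(n_starts=3, seed=0, xatol=1e-6, fatol=1e-6)
    assert res.converged
    text = res.summary()
    assert "p1" in text and "sigma" in text
    w = res.weights(0)
    assert w.sum() == pytest.approx(1.0)
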