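import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from mirrormix import (
    SMCParams,
    daynight_score,
    memory_rate,
    participant_stage_counts,
    probit_regression,
    simulate_dataset,
    slice_sample_smc,
    slice_sampler,
    stage_outcomes,
)


# ---------------------------------------------------------------------------
# memory rate
# ---------------------------------------------------------------------------


def test_memory_rate_worked_example():
    # 60% correct with two options -> remembering on 20% of trials
    assert memory_rate(0.6, 0.5) == pytest.approx(0.2)


@pytest.mark.parametrize("chance", [0.5, 1 / 3, 0.125])
def test_memory_rate_anchors(chance):
    assert memory_rate(chance, chance) == pytest.approx(0.0)
    assert memory_rate(1.0, chance) == pytest.approx(1.0)


def test_memory_rate_inverts_guessing_mixture():
    rng = np.random.default_rng(0)
    for _ in range(50):
        chance = rng.uniform(0, 0.9)
        m = rng.uniform(-chance / (1 - chance), 1)
        p = chance + m * (1 - chance)
        assert memory_rate(p, chance) == pytest.approx(m, abs=1e-12)


def test_memory_rate_rejects_degenerate_chance():
    with pytest.raises(ValueError):
        memory_rate(0.5, 1.0)


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------


def test_slice_sampler_matches_conjugate_beta():
    """Bernoulli likelihood + flat prior == Beta(k+1, n-k+1) posterior."""
    k, n = 20, 50

    def logf(x):
        p = x[0]
        if p <= 0 or p >= 1:
            return -np.inf
        return k * math.log(p) + (n - k) * math.log(1 - p)

    rng = np.random.default_rng(12)
    draws = slice_sampler(logf, np.array([0.5]), np.array([0.2]),
                          np.array([0.0]), np.array([1.0]), 4000, rng)[:, 0]
    post = beta_dist(k + 1, n - k + 1)
    # slice chains on a unimodal 1-D target mix fast; allow 3 MC SEs with a
    # conservative effective sample size of n/10
    mc_se = post.std() / math.sqrt(len(draws) / 10)
    assert abs(draws.mean() - post.mean()) < 3 * mc_se
    assert draws.std() == pytest.approx(post.std(), rel=0.15)


def test_slice_sampler_requires_finite_init():
    with pytest.raises(ValueError):
        slice_sampler(lambda x: -np.inf, np.array([0.5]), np.array([0.1]),
                      np.array([0.0]), np.array([1.0]), 10,
                      np.random.default_rng(0))


def test_slice_sample_smc_recovers_parameters(arctic):
    truth = SMCParams(p1=0.8, p2=0.75, p3=0.6, sigma=0.15)
    trials = simulate_dataset("smc", truth, arctic, 2000, seed=3)
    chain = slice_sample_smc(trials, arctic, n_samples=600, seed=4,
                             mle_starts=3)
    means = chain.mean()
    assert means["p1"] == pytest.approx(0.8, abs=0.05)
    assert means["p2"] == pytest.approx(0.75, abs=0.05)
    assert means["p3"] == pytest.approx(0.6, abs=0.05)
    assert means["sigma"] == pytest.approx(0.15, abs=0.02)
    ci = chain.credible_interval()
    assert (ci["lower"] <= ci["upper"]).all()


def test_slice_sample_smc_deterministic(arctic, smc_trials_small):
    a = slice_sample_smc(smc_trials_small, arctic, n_samples=50, seed=8,
                         mle_starts=2)
    b = slice_sample_smc(smc_trials_small, arctic, n_samples=50, seed=8,
                         mle_starts=2)
    assert a.samples.equals(b.samples)


def test_memory_rates_transform_of_chain(arctic, smc_trials_small):
    chain = slice_sample_smc(smc_trials_small, arctic, n_samples=50, seed=8,
                             mle_starts=2)
    rates = chain.memory_rates(arctic)
    assert set(rates.columns) == {"p1", "p2", "p3"}
    expected = (chain.samples["p1"] - 0.5) / 0.5
    assert np.allclose(rates["p1"], expected)


# ---------------------------------------------------------------------------
# stage outcomes
# ---------------------------------------------------------------------------


def _trial_at(point, target_id, pid=0):
    return pd.DataFrame({"participant_id": [pid], "target_id": [target_id],
                         "response_x_m": [point[0]], "response_y_m": [point[1]]})


def test_stage_outcomes_at_true_centre(arctic):
    t = arctic.targets[5]
    out = stage_outcomes(arctic, _trial_at(t.position, t.id))
    assert out.iloc[0]["landmark_correct"]
    assert out.iloc[0]["category_correct"] is np.True_ or out.iloc[0]["category_correct"]
    assert out.iloc[0]["mirror_correct"]


def test_stage_outcomes_at_mirror(arctic):
    t = arctic.targets[5]
    mirror = arctic.target(t.mirror_id)
    out = stage_outcomes(arctic, _trial_at(mirror.position, t.id))
    row = out.iloc[0]
    assert row["landmark_correct"] and row["category_correct"]
    assert not row["mirror_correct"]


def test_stage_outcomes_other_landmark(arctic):
    t = arctic.targets[5]  # landmark 1
    other = next(u for u in arctic.targets if u.landmark_id != t.landmark_id)
    out = stage_outcomes(arctic, _trial_at(other.position, t.id))
    row = out.iloc[0]
    assert not row["landmark_correct"]
    assert pd.isna(row["category_correct"]) and pd.isna(row["mirror_correct"])


def test_stage_outcomes_jetty_has_no_category(jetty):
    t = jetty.targets[0]
    out = stage_outcomes(jetty, _trial_at(t.position, t.id))
    assert pd.isna(out.iloc[0]["category_correct"])
    assert out.iloc[0]["mirror_correct"]


def test_participant_stage_counts(arctic):
    t = arctic.targets[5]
    mirror = arctic.target(t.mirror_id)
    trials = pd.concat([
        _trial_at(t.position, t.id, pid=1),
        _trial_at(mirror.position, t.id, pid=1),
        _trial_at(arctic.targets[0].position, t.id, pid=1),
    ], ignore_index=True)
    counts = participant_stage_counts(arctic, trials)
    row = counts.loc[1]
    assert row["p1_n"] == 3 and row["p1_k"] == 2
    assert row["p2_n"] == 2 and row["p2_k"] == 2
    assert row["p3_n"] == 2 and row["p3_k"] == 1


# ---------------------------------------------------------------------------
# Day-Night score
# ---------------------------------------------------------------------------


def test_daynight_identical_times_contribute_zero():
    s = daynight_score([10.0, 10.0, 10.0], [0, 1, 2])
    s_err_only = daynight_score([5.0, 5.0, 5.0], [0, 1, 2])
    assert np.allclose(s, s_err_only)


def test_daynight_mean_zero_and_monotone():
    times = [12.0, 15.0, 20.0, 30.0]
    errors = [0, 1, 2, 5]
    s = daynight_score(times, errors)
    assert s.mean() == pytest.approx(0.0, abs=1e-12)
    assert (np.diff(s) > 0).all()  # strictly slower & sloppier scores higher


def test_daynight_requires_two_entries():
    with pytest.raises(ValueError):
        daynight_score([1.0], [0])


# ---------------------------------------------------------------------------
# probit regression
# ---------------------------------------------------------------------------


def _synthetic_counts(mu, b, Z, n_trials, rng):
    eta = mu + Z @ b + rng.normal(0, 0.1, size=len(Z))
    p = norm.cdf(eta)
    k = rng.binomial(n_trials, p)
    return pd.DataFrame({"p1_k": k, "p1_n": n_trials})


def test_probit_regression_recovers_mu(arctic):
    rng = np.random.default_rng(7)
    n = 64
    Z = pd.DataFrame(rng.standard_normal((n, 3)),
                     columns=["age", "vocabulary", "daynight"])
    counts = _synthetic_counts(0.6, np.zeros(3), Z.to_numpy(), 16, rng)
    counts.index = Z.index
    res = probit_regression(counts, Z, n_chains=2, n_samples=700, burnin=200,
                            seed=1, stages=("p1",))
    tab = res.summaries["p1"]
    assert tab.loc["mu", "ci95_lower"] < 0.6 < tab.loc["mu", "ci95_upper"]
    # zero coefficients should not be detected
    for name in ("b_age", "b_vocabulary"):
        assert tab.loc[name, "ci95_lower"] < 0 < tab.loc[name, "ci95_upper"]
    # 99.5% interval contains the 95% interval
    assert tab.loc["mu", "ci995_lower"] <= tab.loc["mu", "ci95_lower"]
    assert tab.loc["mu", "ci995_upper"] >= tab.loc["mu", "ci95_upper"]
    assert (tab["rhat"] < 1.1).all()


def test_probit_regression_deterministic():
    rng = np.random.default_rng(3)
    Z = pd.DataFrame(rng.standard_normal((20, 3)),
                     columns=["age", "vocabulary", "daynight"])
    counts = _synthetic_counts(0.0, np.array([0.3, 0, 0]), Z.to_numpy(), 10, rng)
    counts.index = Z.index
    a = probit_regression(counts, Z, n_chains=2, n_samples=200, burnin=50,
                          seed=5, stages=("p1",))
    b = probit_regression(counts, Z, n_chains=2, n_samples=200, burnin=50,
                          seed=5, stages=("p1",))
    assert np.allclose(a.chains["p1"], b.chains["p1"])


def test_probit_regression_validates_counts():
    Z = pd.DataFrame(np.zeros((3, 3)), columns=["age", "vocabulary", "daynight"])
    counts = pd.DataFrame({"p1_k": [5, 0, 0], "p1_n": [4, 4, 4]})
    with pytest.raises(ValueError):
        probit_regression(counts, Z, n_chains=1, n_samples=20, burnin=5,
                          stages=("p1",))
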