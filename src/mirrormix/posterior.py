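"""Bayesian estimation for the stage-tree model and its covariate regression.

Two samplers live here.  The stage-tree parameters (p1, p2 where the layout
has side targets, p3, sigma) are drawn coordinate-wise by univariate slice
sampling with flat priors on [0, 1] for the probabilities and a flat prior on
log sigma, initialised at the maximum-likelihood estimate.  The covariate
analysis is a Bayesian probit regression: each participant's stage
probability is Phi(mu + b1*Z_age + b2*Z_vocab + b3*Z_daynight + E_i) with a
participant-level normal error E_i of precision tau, an Exponential(mean 100)
prior on tau and flat priors elsewhere; the Bernoulli observations are the
per-trial stage outcomes classified by the nearest-target rule.

Posterior p-parameters are reported as *memory rates*: the guessing-corrected
probability m = (p_correct - chance) / (1 - chance), which is 0 at chance and
1 at perfect recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .layouts import Layout, nearest_target
from .response_models import SingleMultiCueModel

__all__ = [
    "PosteriorChain",
    "RegressionResult",
    "slice_sampler",
    "slice_sample_smc",
    "memory_rate",
    "stage_outcomes",
    "participant_stage_counts",
    "daynight_score",
    "probit_regression",
]


# ---------------------------------------------------------------------------
# slice sampling
# ---------------------------------------------------------------------------


def _slice_update_scalar(logf, x, lx, w, lo, hi, rng, max_steps=100):
    """One stepping-out/shrinkage slice-sampling update of a scalar."""
    y = lx + math.log(rng.uniform())
    L = x - w * rng.uniform()
    R = L + w
    steps = max_steps
    while L > lo and steps > 0 and logf(max(L, lo)) > y:
        L -= w
        steps -= 1
    L = max(L, lo)
    steps = max_steps
    while R < hi and steps > 0 and logf(min(R, hi)) > y:
        R += w
        steps -= 1
    R = min(R, hi)
    while True:
        x1 = rng.uniform(L, R)
        lx1 = logf(x1)
        if lx1 >= y:
            return x1, lx1
        if x1 < x:
            L = x1
        else:
            R = x1


def slice_sampler(logf, x0: np.ndarray, widths: np.ndarray,
                  lower: np.ndarray, upper: np.ndarray,
                  n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Coordinate-wise slice sampling of a log density over a box.

    Returns an (n_samples, d) array.  ``lower``/``upper`` may be ±inf; the
    density must be finite at ``x0``.
    """
    x = np.array(x0, dtype=float)
    d = len(x)
    lx = logf(x)
    if not np.isfinite(lx):
        raise ValueError("log density not finite at the initial point")
    out = np.empty((n_samples, d))
    for s in range(n_samples):
        for j in range(d):
            def logf_j(v, j=j):
                xt = x.copy()
                xt[j] = v
                return logf(xt)
            x[j], lx = _slice_update_scalar(
                logf_j, x[j], lx, widths[j], lower[j], upper[j], rng)
        out[s] = x
    return out


def _slice_update_independent(logf_vec, x, lx, w, lo, hi, rng, max_steps=100):
    """Vectorised slice update for n conditionally independent scalars."""
    n = x.shape[0]
    y = lx + np.log(rng.uniform(size=n))
    L = x - w * rng.uniform(size=n)
    R = L + w
    for _ in range(max_steps):
        grow = (L > lo) & (logf_vec(np.maximum(L, lo)) > y)
        if not grow.any():
            break
        L[grow] -= w
    L = np.maximum(L, lo)
    for _ in range(max_steps):
        grow = (R < hi) & (logf_vec(np.minimum(R, hi)) > y)
        if not grow.any():
            break
        R[grow] += w
    R = np.minimum(R, hi)
    x1 = np.array(x)
    lx1 = np.array(lx)
    todo = np.ones(n, bool)
    while todo.any():
        prop = rng.uniform(L, R)
        lp = logf_vec(prop)
        accept = todo & (lp >= y)
        x1[accept] = prop[accept]
        lx1[accept] = lp[accept]
        todo &= ~accept
        shrink_left = todo & (prop < x)
        L[shrink_left] = prop[shrink_left]
        shrink_right = todo & ~shrink_left
        R[shrink_right] = prop[shrink_right]
    return x1, lx1


# ---------------------------------------------------------------------------
# posterior over the stage-tree parameters
# ---------------------------------------------------------------------------


@dataclass
class PosteriorChain:
    """Slice-sampling draws of the stage-tree parameters."""

    samples: pd.DataFrame  # columns: p1, (p2,) p3, sigma
    init: dict[str, float]
    seed: int
    layout_name: str

    def mean(self) -> pd.Series:
        return self.samples.mean()

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        a = (1.0 - level) / 2.0
        q = self.samples.quantile([a, 1.0 - a]).T
        q.columns = ["lower", "upper"]
        return q

    def memory_rates(self, layout: Layout) -> pd.DataFrame:
        """Transform the p-parameter draws to guessing-corrected memory rates.

        Chance levels: p1 -> 1/n_landmarks; p2, p3 -> 1/2.
        """
        rates = {}
        for col in self.samples.columns:
            if col == "sigma":
                continue
            chance = layout.chance_p1 if col == "p1" else 0.5
            rates[col] = memory_rate(self.samples[col].to_numpy(), chance)
        return pd.DataFrame(rates, index=self.samples.index)


def slice_sample_smc(trials: pd.DataFrame, layout: Layout, n_samples: int = 10_000,
                     seed: int = 0, burn_frac: float = 0.1,
                     mle_starts: int = 10) -> PosteriorChain:
    """Posterior draws for the stage-tree model on one trial table.

    Coordinate-wise slice sampling of the likelihood with flat priors on
    [0, 1] for the probabilities and a flat prior on log sigma, seeded at the
    maximum-likelihood estimate.  The first ``burn_frac`` of the chain is
    discarded (the returned frame has ``n_samples`` retained draws).
    """
    model = SingleMultiCueModel(trials, layout)
    mle = model.fit(n_starts=mle_starts, seed=seed)
    names = [n for n in model.param_names if n != "sigma"]
    x0 = np.array([mle.params[n] for n in names] + [math.log(mle.params["sigma"])])
    d = len(x0)
    lower = np.array([0.0] * (d - 1) + [-12.0])
    upper = np.array([1.0] * (d - 1) + [3.0])
    widths = np.array([0.2] * (d - 1) + [0.5])

    def logf(x):
        values = {n: x[i] for i, n in enumerate(names)}
        values["sigma"] = math.exp(x[-1])
        ll = model.loglike(values)
        return ll if np.isfinite(ll) else -np.inf

    rng = np.random.default_rng(seed)
    n_burn = int(round(burn_frac * n_samples))
    draws = slice_sampler(logf, x0, widths, lower, upper, n_samples + n_burn, rng)
    draws = draws[n_burn:]
    frame = pd.DataFrame(draws, columns=names + ["sigma"])
    frame["sigma"] = np.exp(frame["sigma"])
    return PosteriorChain(samples=frame, init=dict(mle.params), seed=seed,
                          layout_name=layout.name)


def memory_rate(p_correct, chance: float):
    """Guessing-corrected recall rate m = (p_correct - chance) / (1 - chance).

    Inverts the mixture p_correct = chance + m * (1 - chance): m = 0 means
    responding at chance, m = 1 perfect recall.
    """
    if not 0.0 <= chance < 1.0:
        raise ValueError(f"chance must lie in [0, 1), got {chance}")
    return (np.asarray(p_correct, dtype=float) - chance) / (1.0 - chance) \
        if np.ndim(p_correct) else (float(p_correct) - chance) / (1.0 - chance)


# ---------------------------------------------------------------------------
# stage classification and covariate scores
# ---------------------------------------------------------------------------


def stage_outcomes(layout: Layout, trials: pd.DataFrame) -> pd.DataFrame:
    """Classify each response into per-stage binary outcomes.

    The response is attributed to its nearest target centre.  Stage outcomes
    mirror the model's stage tree: was the nearest target by the correct
    landmark; given that, did it have the correct side/end relation (only in
    layouts with side targets); given both, was it exactly the correct target
    (rather than its local mirror).  Later stages are undefined (pd.NA) when
    an earlier stage failed.
    """
    rows = []
    for _, tr in trials.iterrows():
        true = layout.target(int(tr["target_id"]))
        resp_tid = nearest_target(layout, (tr["response_x_m"], tr["response_y_m"]))
        resp = layout.target(resp_tid)
        lm_ok = resp.landmark_id == true.landmark_id
        if layout.has_side_targets:
            cat_ok = (resp.relation == true.relation) if lm_ok else pd.NA
            both = lm_ok and cat_ok is True
        else:
            cat_ok = pd.NA
            both = lm_ok
        mir_ok = (resp_tid == true.id) if both else pd.NA
        rows.append((lm_ok, cat_ok, mir_ok))
    return pd.DataFrame(
        rows, index=trials.index,
        columns=["landmark_correct", "category_correct", "mirror_correct"],
    ).astype({"landmark_correct": bool, "category_correct": "boolean",
              "mirror_correct": "boolean"})


def participant_stage_counts(layout: Layout, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant Bernoulli counts (successes k, defined trials n) per stage."""
    out = stage_outcomes(layout, trials)
    out = out.assign(participant_id=trials["participant_id"].to_numpy())
    stages = {"p1": "landmark_correct", "p2": "category_correct",
              "p3": "mirror_correct"}
    agg = {}
    for p, col in stages.items():
        grp = out.groupby("participant_id")[col]
        agg[f"{p}_k"] = grp.apply(lambda s: int(s.dropna().astype(bool).sum()))
        agg[f"{p}_n"] = grp.apply(lambda s: int(s.notna().sum()))
    return pd.DataFrame(agg)


def daynight_score(times, errors) -> np.ndarray:
    """Combined inhibition/working-memory score from the reversed round.

    Rank each measure (average ranks on ties, robust to outliers), z-score the
    ranks, and sum.  A component with no variance contributes zero.
    """
    times = np.asarray(times, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if times.shape != errors.shape or times.ndim != 1 or len(times) < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")

    def rank_z(v):
        r = rankdata(v, method="average")
        sd = r.std()
        return np.zeros_like(r) if sd == 0 else (r - r.mean()) / sd

    return rank_z(times) + rank_z(errors)


# ---------------------------------------------------------------------------
# Bayesian probit regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Posterior summaries of the probit regression, per stage parameter.

    ``summaries[stage]`` is a DataFrame with rows mu, b_age, b_vocabulary,
    b_daynight, tau and columns mean/sd/ci95/ci995 bounds plus split-R̂ and
    effective sample size; ``flagged`` marks stages whose worst split-R̂
    exceeded 1.1.
    """

    summaries: dict[str, pd.DataFrame]
    chains: dict[str, np.ndarray]  # (n_chains, n_draws, 5): mu, b1..b3, tau
    flagged: dict[str, bool]
    n_chains: int
    n_samples: int
    burnin: int
    seed: int
    predictors: tuple[str, ...] = ("age", "vocabulary", "daynight")

    def summary(self) -> str:
        lines = []
        for stage, tab in self.summaries.items():
            lines.append(f"stage {stage}"
                         + ("  [non-mixing flagged]" if self.flagged[stage] else ""))
            lines.append(tab.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


_PARAM_ROWS = ("mu", "b_age", "b_vocabulary", "b_daynight", "tau")


def probit_regression(counts: pd.DataFrame, Z: pd.DataFrame,
                      n_chains: int = 4, n_samples: int = 5000,
                      burnin: int = 1000, seed: int = 0,
                      stages: tuple[str, ...] = ("p1", "p2", "p3")) -> RegressionResult:
    """Relate per-participant stage probabilities to covariate z-scores.

    ``counts`` comes from :func:`participant_stage_counts`; ``Z`` has columns
    ``age``, ``vocabulary``, ``daynight`` aligned on the same participants.
    For each stage, participant i's success probability is
    ``Phi(mu + Z_i · b + E_i)`` with ``E_i ~ N(0, 1/tau)``,
    ``tau ~ Exponential(mean 100)`` and flat priors on mu and b.  Sampling is
    slice-within-Gibbs (tau has a conjugate Gamma update).
    """
    if not counts.index.equals(Z.index):
        raise ValueError("counts and Z must be indexed by the same participants")
    Zm = Z[["age", "vocabulary", "daynight"]].to_numpy(dtype=float)
    n = len(Zm)
    master = np.random.SeedSequence(seed)
    summaries, chain_store, flagged = {}, {}, {}
    for stage in stages:
        k = counts[f"{stage}_k"].to_numpy(dtype=float)
        m = counts[f"{stage}_n"].to_numpy(dtype=float)
        if np.any(k > m):
            raise ValueError(f"stage {stage}: successes exceed trials")
        chains = np.empty((n_chains, n_samples - burnin, 5))
        for c, ss in enumerate(master.spawn(n_chains)):
            chains[c] = _probit_chain(k, m, Zm, n_samples, burnin,
                                      np.random.default_rng(ss))
        tab = _summarise_chains(chains)
        summaries[stage] = tab
        chain_store[stage] = chains
        flagged[stage] = bool((tab["rhat"] > 1.1).any())
    return RegressionResult(summaries=summaries, chains=chain_store,
                            flagged=flagged, n_chains=n_chains,
                            n_samples=n_samples, burnin=burnin, seed=seed)


def _probit_chain(k, m, Z, n_samples, burnin, rng):
    n = len(k)

    def loglik(mu, b, E):
        eta = mu + Z @ b + E
        return (k * norm.logcdf(eta) + (m - k) * norm.logcdf(-eta)).sum()

    def loglik_vec_E(Evec, mu, b):
        eta = mu + Z @ b + Evec
        return k * norm.logcdf(eta) + (m - k) * norm.logcdf(-eta)

    p_bar = np.clip(k.sum() / max(m.sum(), 1.0), 0.02, 0.98)
    mu = float(norm.ppf(p_bar)) + 0.5 * rng.standard_normal()
    b = 0.1 * rng.standard_normal(3)
    E = np.zeros(n)
    tau = 1.0
    out = np.empty((n_samples - burnin, 5))
    for s in range(n_samples):
        lx = loglik(mu, b, E)
        mu, lx = _slice_update_scalar(
            lambda v: loglik(v, b, E), mu, lx, 0.5, -8.0, 8.0, rng)
        for j in range(3):
            def logf(v, j=j):
                bt = b.copy()
                bt[j] = v
                return loglik(mu, bt, E)
            b[j], lx = _slice_update_scalar(logf, b[j], lx, 0.5, -8.0, 8.0, rng)
        # E_i are conditionally independent given (mu, b, tau)
        lE = loglik_vec_E(E, mu, b) - 0.5 * tau * E**2
        width = max(2.0 / math.sqrt(tau), 0.1)
        E, _ = _slice_update_independent(
            lambda v: loglik_vec_E(v, mu, b) - 0.5 * tau * v**2,
            E, lE, width, -20.0, 20.0, rng)
        # conjugate update: Gamma(n/2 + 1, sum(E^2)/2 + 1/100)
        tau = rng.gamma(shape=n / 2.0 + 1.0, scale=1.0 / (0.5 * (E**2).sum() + 0.01))
        if s >= burnin:
            out[s - burnin] = (mu, b[0], b[1], b[2], tau)
    return out


def _summarise_chains(chains: np.ndarray) -> pd.DataFrame:
    import arviz as az

    flat = chains.reshape(-1, chains.shape[-1])
    rows = []
    idata = az.from_dict({name: chains[:, :, i]
                          for i, name in enumerate(_PARAM_ROWS)})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    for i, name in enumerate(_PARAM_ROWS):
        v = flat[:, i]
        lo95, hi95 = np.quantile(v, [0.025, 0.975])
        lo995, hi995 = np.quantile(v, [0.0025, 0.9975])
        rows.append({
            "mean": v.mean(), "sd": v.std(ddof=1),
            "ci95_lower": lo95, "ci95_upper": hi95,
            "ci995_lower": lo995, "ci995_upper": hi995,
            "rhat": float(rhat[name].values), "ess": float(ess[name].values),
        })
    return pd.DataFrame(rows, index=list(_PARAM_ROWS))
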