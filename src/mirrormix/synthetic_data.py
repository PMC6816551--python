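"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure of the two developmental
datasets: participants arrive in age bins with the study's bin sizes, complete
the per-design number of pointing trials (16 near + 8 far in the two-landmark
"arctic" arena, 14 near + 16 far in the three-landmark "jetty"), and their
responses are drawn from a chosen generating model.  Covariates (vocabulary
raw score, Day-Night time and errors) are generated per participant and can
drive the stage probabilities through the same probit link the regression
analysis assumes, so the whole pipeline — fitting, selection, posterior
estimation, regression — is testable end to end without any deposited data.

Far trials are generated (and flagged ``far``) purely for schema fidelity;
they carry the sentinel target id and are excluded from every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import Dataset, FAR_TARGET_ID, read_dataset, write_dataset
from .layouts import Layout, canonical_layout
from .posterior import daynight_score
from .response_models import SMCParams, make_model

__all__ = ["ProbitLink", "CohortConfig", "generate_cohort", "roundtrip"]

# near-trial allocation per design: target id -> repeats per participant
_NEAR_ALLOCATION = {
    # every target shown twice: 16 near trials
    "arctic": {t: 2 for t in range(8)},
    # 14 near trials over 6 end targets; the first landmark's ends get 2 each,
    # the remaining 10 go round-robin over the other four targets
    "jetty": {0: 2, 1: 2, 2: 3, 3: 2, 4: 3, 5: 2},
}
_N_FAR = {"arctic": 8, "jetty": 16}
_ROTATIONS = {
    "arctic": (30, 40, 50, 60, 105, 125, 145, 165),
    "jetty": (45, 60, 75, 110, 140, 170),
}
_DEFAULT_BINS = {
    "arctic": {(3.5, 4.5): 33, (4.5, 5.5): 35},
    "jetty": {(4.5, 5.5): 12, (5.5, 6.5): 15, (6.5, 8.5): 9},
}
# Default stage probabilities per age bin, anchored to the published fits and
# correct-landmark rates (0.79/0.77/0.61 for the youngest two-landmark group;
# landmark rates 69/67/97% in the three-landmark arena).
_DEFAULT_PARAMS = {
    "arctic": {
        (3.5, 4.5): SMCParams(p1=0.79, p2=0.77, p3=0.61, sigma=0.25),
        (4.5, 5.5): SMCParams(p1=0.90, p2=0.85, p3=0.60, sigma=0.22),
    },
    "jetty": {
        (4.5, 5.5): SMCParams(p1=0.55, p3=0.60, sigma=0.25),
        (5.5, 6.5): SMCParams(p1=0.52, p3=0.65, sigma=0.24),
        (6.5, 8.5): SMCParams(p1=0.95, p3=0.80, sigma=0.18),
    },
}


@dataclass(frozen=True)
class ProbitLink:
    """Ground-truth probit link from covariate z-scores to stage probabilities.

    ``p_stage_i = Phi(mu[stage] + betas[stage] · Z_i + E_i)`` with
    ``E_i ~ Normal(0, 1/tau)``; Z columns are (age, vocabulary, daynight).
    """

    mu: Mapping[str, float]
    betas: Mapping[str, tuple[float, float, float]]
    tau: float = 25.0


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the published designs: bin sizes 33/35 (arctic,
    528/560 near trials) and 12/15/9 (jetty, 14 near trials each), responses
    from the stage-tree model at the published parameter scale.
    """

    environment: str = "arctic"
    n_participants: Mapping[tuple[float, float], int] | None = None
    family: str = "smc"
    params_by_bin: Mapping[tuple[float, float], object] | None = None
    link: ProbitLink | None = None
    sigma: float = 0.25  # used with `link`
    include_far: bool = True
    seed: int = 0

    def bins(self) -> dict[tuple[float, float], int]:
        return dict(self.n_participants or _DEFAULT_BINS[self.environment])

    def bin_params(self) -> dict:
        if self.params_by_bin is not None:
            return dict(self.params_by_bin)
        if self.family != "smc":
            raise ValueError("params_by_bin is required for non-default families")
        return {b: _DEFAULT_PARAMS[self.environment][b] for b in self.bins()}


def generate_cohort(config: CohortConfig) -> Dataset:
    """Generate trials and covariates for one synthetic cohort.

    Deterministic given ``config.seed``.  The returned dataset carries a
    ``ground_truth`` record (generating family, per-participant parameters)
    for recovery checks.
    """
    layout = canonical_layout(config.environment)
    alloc = _NEAR_ALLOCATION[config.environment]
    if set(alloc) != set(layout.target_ids):
        raise ValueError("near-trial allocation does not match the layout")
    rng = np.random.default_rng(config.seed)
    bins = config.bins()

    participants = _draw_covariates(bins, rng)
    n = len(participants)
    Z = pd.DataFrame({
        "age": _zscore(participants["age_years"]),
        "vocabulary": _zscore(participants["vocabulary_raw"]),
        "daynight": daynight_score(participants["daynight_time_s"],
                                   participants["daynight_errors"]),
    }, index=participants.index)

    per_participant = _participant_params(config, participants, Z, rng)

    trial_frames = []
    truth_rows = []
    for i, row in participants.iterrows():
        pid = int(row["participant_id"])
        params = per_participant[pid]
        trial_frames.append(_participant_trials(
            config, layout, alloc, pid, float(row["age_years"]), params, rng))
        rec = {"participant_id": pid}
        rec.update({k: v for k, v in _params_record(params).items()})
        truth_rows.append(rec)
    trials = pd.concat(trial_frames, ignore_index=True)
    ground_truth = {
        "environment": config.environment,
        "family": config.family,
        "seed": config.seed,
        "link": None if config.link is None else {
            "mu": dict(config.link.mu),
            "betas": {k: list(v) for k, v in config.link.betas.items()},
            "tau": config.link.tau,
        },
        "participants": truth_rows,
    }
    return Dataset(trials=trials, participants=participants,
                   ground_truth=ground_truth)


def roundtrip(dataset: Dataset, path) -> Dataset:
    """Write then re-read a dataset, asserting value equality."""
    write_dataset(dataset, path)
    back = read_dataset(path, format="csv")
    if not dataset.equals(back):
        raise AssertionError("dataset changed across write/read roundtrip")
    return back


# ---------------------------------------------------------------------------


def _zscore(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd


def _draw_covariates(bins, rng) -> pd.DataFrame:
    rows = []
    pid = 0
    for (lo, hi), count in sorted(bins.items()):
        for _ in range(count):
            age = rng.uniform(lo, hi)
            # vocabulary grows with age; Day-Night gets faster and cleaner
            vocab = max(0.0, round(20 + 12 * (age - 3.5) + 6 * rng.standard_normal()))
            inhibition = rng.standard_normal()  # latent skill, higher = better
            time_s = 20.0 + 10.0 * np.exp(-0.4 * inhibition
                                          + 0.2 * rng.standard_normal())
            errors = rng.poisson(np.exp(1.0 - 0.5 * inhibition))
            rows.append((pid, age, vocab, round(time_s, 1), errors))
            pid += 1
    from .io import PARTICIPANT_COLUMNS

    return pd.DataFrame(rows, columns=["participant_id", "age_years",
                                       "vocabulary_raw", "daynight_time_s",
                                       "daynight_errors"]).astype(PARTICIPANT_COLUMNS)


def _participant_params(config, participants, Z, rng) -> dict[int, object]:
    layout_has_sides = config.environment == "arctic"
    out = {}
    if config.link is not None:
        if config.family != "smc":
            raise ValueError("the probit link applies to the stage-tree family")
        Zm = Z[["age", "vocabulary", "daynight"]].to_numpy(float)
        stages = ("p1", "p2", "p3") if layout_has_sides else ("p1", "p3")
        probs = {}
        for stage in stages:
            eta = (config.link.mu[stage] + Zm @ np.asarray(config.link.betas[stage])
                   + rng.normal(0.0, 1.0 / np.sqrt(config.link.tau), size=len(Zm)))
            probs[stage] = norm.cdf(eta)
        for j, (_, row) in enumerate(participants.iterrows()):
            pid = int(row["participant_id"])
            out[pid] = SMCParams(
                p1=float(probs["p1"][j]),
                p2=float(probs["p2"][j]) if layout_has_sides else None,
                p3=float(probs["p3"][j]),
                sigma=config.sigma,
            )
        return out
    bin_params = config.bin_params()
    for _, row in participants.iterrows():
        pid = int(row["participant_id"])
        age = float(row["age_years"])
        for (lo, hi), params in sorted(bin_params.items()):
            top = max(b[1] for b in bin_params)
            if lo <= age < hi or (hi == top and age == hi):
                out[pid] = params
                break
        else:
            raise ValueError(f"no parameter bin covers age {age}")
    return out


def _participant_trials(config, layout: Layout, alloc, pid, age, params, rng):
    env = config.environment
    target_ids = [t for t in sorted(alloc) for _ in range(alloc[t])]
    probe = pd.DataFrame({"target_id": [layout.target_ids[0]],
                          "response_x_m": [0.0], "response_y_m": [0.0]})
    model = make_model(config.family, probe, layout)
    resp = model.simulate(params, target_ids, rng)
    records = [
        (pid, age, env, t, float(resp[j, 0]), float(resp[j, 1]), "near")
        for j, t in enumerate(target_ids)
    ]
    if config.include_far:
        for _ in range(_N_FAR[env]):
            # far targets carry no modelled geometry: a broad scatter in the
            # arena is enough for schema fidelity
            r = layout.arena_radius * np.sqrt(rng.uniform())
            a = rng.uniform(0, 2 * np.pi)
            records.append((pid, age, env, FAR_TARGET_ID,
                            float(r * np.cos(a)), float(r * np.sin(a)), "far"))
    df = pd.DataFrame(records, columns=["participant_id", "age_years",
                                        "environment", "target_id",
                                        "response_x_m", "response_y_m",
                                        "trial_type"])
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df.insert(3, "trial_index", np.arange(len(df)))
    df["rotation_deg"] = rng.choice(_ROTATIONS[env], size=len(df)).astype(float)
    return df[["participant_id", "age_years", "environment", "trial_index",
               "target_id", "response_x_m", "response_y_m", "rotation_deg",
               "trial_type"]]


def _params_record(params) -> dict:
    if hasattr(params, "__dataclass_fields__"):
        return {k: getattr(params, k) for k in params.__dataclass_fields__}
    return dict(params)
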