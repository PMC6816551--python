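"""Cross-validated model selection.

Models are compared by leave-one-target-out cross-validation: parameters are
fitted by maximum likelihood to the trials of all-but-one target, the held-out
target's trials are scored by the negative log probability the fitted model
assigns them, and the per-fold scores are summed.  Lower totals are better; a
difference of ``log(100) ~ 4.6`` between totals means the winning model made
the held-out data about 100 times more probable overall.

The exhaustive structured-noise search enumerates every three-level nested
partition of the 8 targets (a 4+4 split, then unordered 2+2 splits: 35 * 3 * 3
= 315 hierarchies) and cross-validates each as a candidate model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layouts import Layout
from .response_models import (
    Hierarchy,
    MixtureFitResults,
    make_model,
)

__all__ = [
    "CVResult",
    "ModelComparison",
    "fit_ml",
    "loto_crossval",
    "fit_restricted_smc",
    "enumerate_structured_hierarchies",
    "compare_models",
]


@dataclass
class CVResult:
    """Leave-one-target-out cross-validation scores for one model.

    ``total`` is the sum over folds of the negative log probability assigned
    to the held-out trials; ``logp`` holds the predicted log probability of
    every trial (each predicted exactly once, by the fold that held it out).
    """

    family: str
    hierarchy: Hierarchy | None
    fold_scores: dict[int, float]
    total: float
    logp: pd.Series
    fold_params: dict[int, dict]
    n_free_params: int
    trial_index: tuple

    @property
    def label(self) -> str:
        if self.hierarchy is None:
            return self.family
        return f"structured:{self.hierarchy.groups}"


def fit_ml(family: str, layout: Layout, trials: pd.DataFrame, *,
           hierarchy: Hierarchy | None = None, fixed=None,
           n_starts: int = 10, seed: int = 0,
           xatol: float = 1e-8, fatol: float = 1e-8) -> MixtureFitResults:
    """Maximum-likelihood fit of one family to a trial table."""
    model = make_model(family, trials, layout, hierarchy=hierarchy, fixed=fixed)
    return model.fit(n_starts=n_starts, seed=seed, xatol=xatol, fatol=fatol)


def loto_crossval(family: str, layout: Layout, trials: pd.DataFrame, *,
                  hierarchy: Hierarchy | None = None, fixed=None,
                  n_starts: int = 10, seed: int = 0,
                  xatol: float = 1e-8, fatol: float = 1e-8) -> CVResult:
    """Leave-one-target-out cross-validation of one model family.

    Folds are defined by the true target id: all trials of one target
    (including repeats) form one test fold, and the model is fitted to the
    remaining targets' trials.
    """
    trials = trials.reset_index(drop=True)
    fold_ids = sorted(trials["target_id"].unique())
    if len(fold_ids) < 2:
        raise ValueError("cross-validation needs trials covering >= 2 targets")
    logp = pd.Series(np.nan, index=trials.index, dtype=float)
    fold_scores: dict[int, float] = {}
    fold_params: dict[int, dict] = {}
    seeds = np.random.SeedSequence(seed).spawn(len(fold_ids))
    for fold_seed, t in zip(seeds, fold_ids):
        test_mask = trials["target_id"] == t
        train = trials[~test_mask]
        if len(train) == 0:
            raise ValueError(f"fold {t}: no training trials")
        res = fit_ml(family, layout, train, hierarchy=hierarchy, fixed=fixed,
                     n_starts=n_starts, seed=int(fold_seed.generate_state(1)[0] % 2**31),
                     xatol=xatol, fatol=fatol)
        test_model = make_model(family, trials[test_mask], layout,
                                hierarchy=hierarchy, fixed=fixed)
        ll = test_model.trial_loglikes(res.params)
        logp[test_mask] = ll
        fold_scores[t] = float(-ll.sum())
        fold_params[t] = dict(res.params)
    assert not logp.isna().any()
    n_free = make_model(family, trials, layout, hierarchy=hierarchy,
                        fixed=fixed).n_free_params
    return CVResult(
        family=family, hierarchy=hierarchy, fold_scores=fold_scores,
        total=float(sum(fold_scores.values())), logp=logp,
        fold_params=fold_params, n_free_params=n_free,
        trial_index=tuple(trials.index),
    )


def fit_restricted_smc(layout: Layout, trials: pd.DataFrame, *,
                       n_starts: int = 10, seed: int = 0,
                       xatol: float = 1e-8, fatol: float = 1e-8) -> CVResult:
    """Cross-validate the landmark-only restriction of the stage-tree model.

    ``p1`` and ``sigma`` stay free; the later stages are pinned to chance
    (``p2 = p3 = 0.5``), i.e. the participant remembers which landmark the
    target was near but nothing further.
    """
    fixed = {"p3": 0.5}
    if layout.has_side_targets:
        fixed["p2"] = 0.5
    return loto_crossval("smc", layout, trials, fixed=fixed,
                         n_starts=n_starts, seed=seed, xatol=xatol, fatol=fatol)


def enumerate_structured_hierarchies(layout: Layout) -> list[Hierarchy]:
    """All distinct three-level hierarchies over a layout's 8 targets.

    C(8,4)/2 = 35 unordered 4+4 splits, times 3 unordered 2+2 splits inside
    each group of four: 315 in total.
    """
    ids = sorted(layout.target_ids)
    if len(ids) != 8:
        raise ValueError(f"structured enumeration needs 8 targets, got {len(ids)}")
    anchor, rest = ids[0], ids[1:]
    hierarchies = []
    for combo in itertools.combinations(rest, 3):
        group_a = (anchor, *combo)
        group_b = tuple(i for i in ids if i not in group_a)
        for pa in _pair_splits(group_a):
            for pb in _pair_splits(group_b):
                hierarchies.append(Hierarchy.from_pairs(pa, pb))
    assert len(set(hierarchies)) == len(hierarchies)
    return hierarchies


def _pair_splits(four: tuple[int, ...]):
    """The 3 unordered ways to split 4 items into two pairs."""
    a, b, c, d = sorted(four)
    return (
        ((a, b), (c, d)),
        ((a, c), (b, d)),
        ((a, d), (b, c)),
    )


@dataclass
class ModelComparison:
    """Pairwise comparison of cross-validation totals.

    ``ratio`` for each model is exp(total - best_total): how many times more
    probable the best model made the held-out data, jointly over all trials.
    """

    table: pd.DataFrame
    best_label: str
    ties: bool
    ratio_threshold: float
    n_within: int

    def summary(self) -> str:
        lines = [f"Cross-validation comparison (best: {self.best_label}"
                 f"{', ties' if self.ties else ''})",
                 f"  models within ratio {self.ratio_threshold:g} of best: "
                 f"{self.n_within}"]
        lines.append(self.table.to_string(
            float_format=lambda v: f"{v:.2f}", max_rows=20))
        return "\n".join(lines)


def compare_models(results: list[CVResult],
                   ratio_threshold: float = 100.0) -> ModelComparison:
    """Rank CV results computed on identical trials.

    Ties on the total score are broken by fewer free parameters, then by
    label, and flagged.
    """
    if len(results) < 2:
        raise ValueError("need at least two results to compare")
    index0 = results[0].trial_index
    for r in results[1:]:
        if r.trial_index != index0:
            raise ValueError("results were computed on different trial sets")
    order = sorted(results, key=lambda r: (r.total, r.n_free_params, r.label))
    best = order[0]
    ties = any(r is not best and r.total == best.total for r in results)
    rows = []
    for r in order:
        delta = r.total - best.total
        rows.append({
            "label": r.label, "family": r.family, "total": r.total,
            "delta": delta, "ratio": float(np.exp(delta)),
            "n_free_params": r.n_free_params,
        })
    table = pd.DataFrame(rows).set_index("label")
    n_within = int((table["ratio"] <= ratio_threshold).sum())
    return ModelComparison(table=table, best_label=best.label, ties=ties,
                           ratio_threshold=ratio_threshold, n_within=n_within)
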