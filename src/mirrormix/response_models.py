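"""Gaussian-mixture response models over target centres.

Every family models a pointing response as a two-stage draw: a categorical
choice of one target's Gaussian component, then an isotropic bivariate normal
displacement with shared standard deviation ``sigma`` (metres).  The families
differ only in how the categorical weights depend on the true target:

``SingleMultiCueModel``
    A stage tree: remember the correct landmark (``p1``), the side/end
    relation on that landmark (``p2``, only in layouts with side targets),
    and finally use the rest of the scene to resolve the landmark's local
    symmetry (``p3``).  Failing the last stage lands on the target's local
    mirror, which is what makes mirror errors a first-class prediction.
``CorrectOrGuessModel``
    Correct component with probability ``pc``; otherwise a uniform guess over
    the remaining targets.
``ExponentialDecayModel``
    Component weights proportional to ``exp(-k d)`` where ``d`` is the
    distance (m) from the true target to each component centre.
``StructuredNoiseModel``
    Any three-level nested partition of 8 targets (4+4, then 2+2, then
    singletons) with stage probabilities ``q1, q2, q3``; the stage tree of
    the single/multi-cue model is one member of this family.

Model classes follow the statsmodels convention: construct from data, call
``.fit()`` for a results object.  The module-level weight functions expose
the same arithmetic for a single true target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import qmc

from .layouts import Layout, pairwise_target_distances

__all__ = [
    "SMCParams",
    "CorrectOrGuessParams",
    "ExpDecayParams",
    "Hierarchy",
    "smc_weights",
    "cog_weights",
    "exp_weights",
    "structured_weights",
    "dataset_nll",
    "sample_response",
    "MixtureResponseModel",
    "SingleMultiCueModel",
    "CorrectOrGuessModel",
    "ExponentialDecayModel",
    "StructuredNoiseModel",
    "MixtureFitResults",
    "make_model",
    "FAMILIES",
]

SIGMA_FLOOR = 1e-4  # m; keeps the likelihood bounded for degenerate data

LOG_2PI = math.log(2.0 * math.pi)


def _row_logsumexp(a: np.ndarray) -> np.ndarray:
    """logsumexp over axis 1; rows must have at least one finite entry.

    Hand-rolled because this sits in the optimiser's inner loop.
    """
    m = a.max(axis=1)
    with np.errstate(invalid="ignore"):
        s = np.exp(a - m[:, None]).sum(axis=1)
    return m + np.log(s)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def _check_prob(name: str, v: float | None) -> None:
    if v is not None and not (0.0 <= v <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SMCParams:
    """Stage probabilities of the single/multi-cue model.

    ``p2`` is ``None`` for layouts without side targets, where the side/end
    stage does not exist.
    """

    p1: float
    p3: float
    sigma: float
    p2: float | None = None

    def __post_init__(self) -> None:
        _check_prob("p1", self.p1)
        _check_prob("p2", self.p2)
        _check_prob("p3", self.p3)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class CorrectOrGuessParams:
    pc: float
    sigma: float

    def __post_init__(self) -> None:
        _check_prob("pc", self.pc)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ExpDecayParams:
    k: float  # per metre
    sigma: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class Hierarchy:
    """Three-level nested partition of 8 target ids.

    ``groups`` is a pair of 4-target groups, each stored as a pair of
    2-target leaf pairs.  The representation is canonicalised (pairs sorted,
    groups sorted by smallest member) so that structurally identical
    hierarchies compare equal regardless of branch order.
    """

    groups: tuple[tuple[tuple[int, int], tuple[int, int]],
                  tuple[tuple[int, int], tuple[int, int]]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", _canonical_groups(self.groups))
        leaves = list(self.leaves())
        if len(leaves) != 8 or len(set(leaves)) != 8:
            raise ValueError("hierarchy must cover 8 distinct targets")

    def leaves(self) -> tuple[int, ...]:
        return tuple(
            t for grp in self.groups for pair in grp for t in pair
        )

    def path(self, target_id: int):
        """(own group, other group, own pair, other pair, sibling) for a leaf."""
        for gi, grp in enumerate(self.groups):
            for pi, pair in enumerate(grp):
                if target_id in pair:
                    other_group = self.groups[1 - gi]
                    other_pair = grp[1 - pi]
                    sibling = pair[0] if pair[1] == target_id else pair[1]
                    return grp, other_group, pair, other_pair, sibling
        raise KeyError(f"target {target_id} not in hierarchy")

    @classmethod
    def from_pairs(cls, group_a: Sequence[Sequence[int]],
                   group_b: Sequence[Sequence[int]]) -> "Hierarchy":
        ga = tuple(tuple(sorted(p)) for p in group_a)
        gb = tuple(tuple(sorted(p)) for p in group_b)
        return cls((ga, gb))

    @classmethod
    def single_multi_cue(cls, layout: Layout) -> "Hierarchy":
        """The landmark → side/end → mirror hierarchy of a 2-landmark layout."""
        if layout.n_targets != 8 or not layout.has_side_targets:
            raise ValueError("canonical stage hierarchy needs 8 targets with sides")
        groups = []
        for lm in layout.landmarks:
            pairs = []
            for rel in ("end", "side"):
                pair = tuple(sorted(
                    t.id for t in layout.targets
                    if t.landmark_id == lm.id and t.relation == rel
                ))
                pairs.append(pair)
            groups.append(tuple(pairs))
        return cls((groups[0], groups[1]))


def _canonical_groups(groups):
    def canon_pair(p):
        a, b = sorted(int(x) for x in p)
        return (a, b)

    def canon_group(g):
        pa, pb = sorted((canon_pair(g[0]), canon_pair(g[1])))
        return (pa, pb)

    ga, gb = sorted((canon_group(groups[0]), canon_group(groups[1])))
    return (ga, gb)


# ---------------------------------------------------------------------------
# component-weight construction
# ---------------------------------------------------------------------------


def _weights_array(layout: Layout) -> np.ndarray:
    return np.zeros(layout.n_targets)


def smc_weights(params: SMCParams, layout: Layout, true_target: int) -> np.ndarray:
    """Mixture weights of the single/multi-cue model for one true target.

    With side targets (8-target layout): correct gets ``p1*p2*p3``, its mirror
    ``p1*p2*(1-p3)``, each same-landmark wrong-relation target
    ``p1*(1-p2)/2``, each other-landmark target ``(1-p1)/4``.  Without side
    targets the ``p2`` stage is skipped.
    """
    t = layout.target(true_target)
    p1, p2, p3 = params.p1, params.p2, params.p3
    if layout.has_side_targets and p2 is None:
        raise ValueError("layout has side targets: p2 is required")
    w = _weights_array(layout)
    other = [i for i, u in enumerate(layout.targets) if u.landmark_id != t.landmark_id]
    w[other] = (1.0 - p1) / len(other)
    ti = layout.target_index(true_target)
    mi = layout.target_index(t.mirror_id)
    if layout.has_side_targets:
        wrong_rel = [
            i for i, u in enumerate(layout.targets)
            if u.landmark_id == t.landmark_id and u.relation != t.relation
        ]
        w[wrong_rel] = p1 * (1.0 - p2) / len(wrong_rel)
        w[ti] = p1 * p2 * p3
        w[mi] = p1 * p2 * (1.0 - p3)
    else:
        w[ti] = p1 * p3
        w[mi] = p1 * (1.0 - p3)
    return w


def cog_weights(params: CorrectOrGuessParams, layout: Layout,
                true_target: int) -> np.ndarray:
    """Correct component ``pc``; every other target ``(1-pc)/(T-1)``."""
    ti = layout.target_index(true_target)
    T = layout.n_targets
    w = np.full(T, (1.0 - params.pc) / (T - 1))
    w[ti] = params.pc
    return w


def exp_weights(params: ExpDecayParams, layout: Layout,
                true_target: int) -> np.ndarray:
    """Weights proportional to ``exp(-k d)``, d = distance to the true target."""
    ti = layout.target_index(true_target)
    d = pairwise_target_distances(layout)[ti]
    w = np.exp(-params.k * d)
    return w / w.sum()


def structured_weights(h: Hierarchy, q1: float, q2: float, q3: float,
                       layout: Layout, true_target: int) -> np.ndarray:
    """Weights of a three-level structured-noise hierarchy.

    At each level the correct branch is taken with probability ``q_level``;
    a failure spreads uniformly over the leaves of the sibling branch.
    """
    for q, nm in ((q1, "q1"), (q2, "q2"), (q3, "q3")):
        _check_prob(nm, q)
    if set(h.leaves()) != set(layout.target_ids):
        raise ValueError("hierarchy leaves do not match layout targets")
    _, other_group, _, other_pair, sibling = h.path(true_target)
    w = _weights_array(layout)
    other_leaves = [layout.target_index(t) for pair in other_group for t in pair]
    w[other_leaves] = (1.0 - q1) / len(other_leaves)
    pair_leaves = [layout.target_index(t) for t in other_pair]
    w[pair_leaves] = q1 * (1.0 - q2) / len(pair_leaves)
    w[layout.target_index(sibling)] = q1 * q2 * (1.0 - q3)
    w[layout.target_index(true_target)] = q1 * q2 * q3
    return w


# ---------------------------------------------------------------------------
# likelihood and sampling
# ---------------------------------------------------------------------------


def _trials_arrays(layout: Layout, trials: pd.DataFrame):
    if len(trials) == 0:
        raise ValueError("empty trial table")
    resp = trials[["response_x_m", "response_y_m"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(resp)):
        raise ValueError("non-finite response coordinates")
    index_of = {tid: i for i, tid in enumerate(layout.target_ids)}
    try:
        tidx = np.array([index_of[t] for t in trials["target_id"]], dtype=int)
    except KeyError as exc:
        raise ValueError(f"trial references unknown target {exc.args[0]}") from None
    return resp, tidx


def _log_mixture_density(resp: np.ndarray, tidx: np.ndarray,
                         W: np.ndarray, centers: np.ndarray,
                         sigma: float) -> np.ndarray:
    """Per-trial log density under the component weights ``W`` (T x T)."""
    d2 = ((resp[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    s2 = sigma * sigma
    with np.errstate(divide="ignore"):
        logw = np.log(W)
    a = logw[tidx] - d2 / (2.0 * s2)
    return logsumexp(a, axis=1) - (LOG_2PI + 2.0 * math.log(sigma))


def dataset_nll(family: str, params, layout: Layout,
                trials: pd.DataFrame, hierarchy: Hierarchy | None = None) -> float:
    """Negative log likelihood of a trial table under one model family.

    ``trials`` needs columns ``target_id``, ``response_x_m``, ``response_y_m``.
    """
    model = make_model(family, trials, layout, hierarchy=hierarchy)
    return model.nll(params)


def _param_value(params, name: str):
    if isinstance(params, Mapping):
        return params[name]
    return getattr(params, name)


def sample_response(family: str, params, layout: Layout, true_target: int,
                    rng: np.random.Generator,
                    hierarchy: Hierarchy | None = None) -> np.ndarray:
    """Draw one response: pick a component by weight, add isotropic noise."""
    w = weights_for(family, params, layout, true_target, hierarchy=hierarchy)
    j = rng.choice(layout.n_targets, p=w)
    sigma = float(_param_value(params, "sigma"))
    return layout.target_positions()[j] + sigma * rng.standard_normal(2)


def weights_for(family: str, params, layout: Layout, true_target: int,
                hierarchy: Hierarchy | None = None) -> np.ndarray:
    if family == "smc":
        return smc_weights(params, layout, true_target)
    if family == "cog":
        return cog_weights(params, layout, true_target)
    if family == "exp":
        return exp_weights(params, layout, true_target)
    if family == "structured":
        if hierarchy is None:
            raise ValueError("structured family needs a hierarchy")
        return structured_weights(
            hierarchy, float(_param_value(params, "q1")),
            float(_param_value(params, "q2")), float(_param_value(params, "q3")),
            layout, true_target)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------


class MixtureResponseModel:
    """Base class: data container + likelihood + maximum-likelihood fit.

    Parameters
    ----------
    trials : pandas.DataFrame
        Columns ``target_id``, ``response_x_m``, ``response_y_m``.
    layout : Layout
    fixed : mapping, optional
        Parameter values pinned during fitting (e.g. ``{"p2": 0.5}``).
    """

    family: str = ""
    _PROB_PARAMS: tuple[str, ...] = ()
    _POS_PARAMS: tuple[str, ...] = ("sigma",)

    def __init__(self, trials: pd.DataFrame, layout: Layout,
                 fixed: Mapping[str, float] | None = None):
        self.layout = layout
        self.trials = trials.reset_index(drop=True)
        self.resp, self.tidx = _trials_arrays(layout, trials)
        centers = layout.target_positions()
        self.d2 = ((self.resp[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(self.param_names)
        if unknown:
            raise ValueError(f"fixed parameters not in model: {sorted(unknown)}")
        self.free_names = tuple(n for n in self.param_names if n not in self.fixed)

    # -- parameterisation ---------------------------------------------------

    @property
    def param_names(self) -> tuple[str, ...]:
        return self._PROB_PARAMS + self._POS_PARAMS

    @property
    def n_free_params(self) -> int:
        return len(self.free_names)

    def weight_matrix(self, values: Mapping[str, float]) -> np.ndarray:
        """(T, T) weights; row i = weights when target i is the true target."""
        raise NotImplementedError

    def params_object(self, values: Mapping[str, float]):
        raise NotImplementedError

    def params_dict(self, params) -> dict[str, float]:
        if isinstance(params, Mapping):
            return dict(params)
        return {n: getattr(params, n) for n in self.param_names}

    # -- likelihood ----------------------------------------------------------

    def trial_loglikes(self, params) -> np.ndarray:
        values = self.params_dict(params)
        W = self.weight_matrix(values)
        sigma = float(values["sigma"])
        s2 = sigma * sigma
        with np.errstate(divide="ignore"):
            logw = np.log(W)
        a = logw[self.tidx] - self.d2 / (2.0 * s2)
        return _row_logsumexp(a) - (LOG_2PI + 2.0 * math.log(sigma))

    def loglike(self, params) -> float:
        return float(self.trial_loglikes(params).sum())

    def nll(self, params) -> float:
        return -self.loglike(params)

    # -- transforms ----------------------------------------------------------

    def _to_natural(self, theta: np.ndarray) -> dict[str, float]:
        values = dict(self.fixed)
        for name, x in zip(self.free_names, theta):
            if name in self._PROB_PARAMS:
                values[name] = float(expit(x))
            elif name == "sigma":
                values[name] = SIGMA_FLOOR + math.exp(min(x, 20.0))
            else:  # positive rate (k)
                values[name] = math.exp(min(x, 20.0))
        return values

    def _to_theta(self, values: Mapping[str, float]) -> np.ndarray:
        theta = []
        for name in self.free_names:
            v = float(values[name])
            if name in self._PROB_PARAMS:
                theta.append(float(logit(np.clip(v, 1e-9, 1 - 1e-9))))
            elif name == "sigma":
                theta.append(math.log(max(v - SIGMA_FLOOR, 1e-12)))
            else:
                theta.append(math.log(max(v, 1e-12)))
        return np.array(theta)

    def _nll_theta(self, theta: np.ndarray) -> float:
        values = self._to_natural(theta)
        sigma = values["sigma"]
        s2 = sigma * sigma
        W = self.weight_matrix(values)
        with np.errstate(divide="ignore"):
            logw = np.log(W)
        a = logw[self.tidx] - self.d2 / (2.0 * s2)
        ll = _row_logsumexp(a).sum() - len(self.tidx) * (LOG_2PI + 2.0 * math.log(sigma))
        if not np.isfinite(ll):
            return 1e12
        return -float(ll)

    # -- starting values ------------------------------------------------------

    def start_params(self) -> dict[str, float]:
        """Method-of-moments start from nearest-target classifications."""
        raise NotImplementedError

    def _sigma_start(self) -> float:
        nearest = self.d2.min(axis=1)
        return float(np.clip(np.sqrt(nearest.mean() / 2.0), 0.02, 1.0))

    def _start_box(self) -> list[tuple[float, float]]:
        box = []
        for name in self.free_names:
            if name in self._PROB_PARAMS:
                box.append((-2.2, 2.2))
            elif name == "sigma":
                box.append((math.log(0.03), math.log(0.8)))
            else:
                box.append((-3.0, 1.5))
        return box

    # -- fitting ---------------------------------------------------------------

    def fit(self, n_starts: int = 10, seed: int = 0,
            xatol: float = 1e-8, fatol: float = 1e-8,
            maxiter: int | None = None) -> "MixtureFitResults":
        """Maximum likelihood by multi-start Nelder–Mead on transformed axes.

        Probabilities are optimised on the log-odds scale and positive
        parameters on the log scale, so the simplex search is unconstrained.
        One start is the method-of-moments estimate; the rest come from a
        seeded Halton design over a broad box in the transformed space.
        """
        starts = [self._to_theta(self.start_params())]
        if n_starts > 1:
            box = self._start_box()
            lo = np.array([b[0] for b in box])
            hi = np.array([b[1] for b in box])
            sampler = qmc.Halton(d=len(box), seed=seed)
            extra = qmc.scale(sampler.random(n_starts - 1), lo, hi)
            starts.extend(list(extra))
        best = None
        n_used = 0
        for theta0 in starts:
            res = optimize.minimize(
                self._nll_theta, theta0, method="Nelder-Mead",
                options=dict(xatol=xatol, fatol=fatol,
                             maxiter=maxiter or 400 * len(theta0),
                             maxfev=maxiter or 400 * len(theta0)),
            )
            n_used += 1
            if best is None or res.fun < best.fun:
                best = res
        values = self._to_natural(best.x)
        converged = bool(np.isfinite(best.fun)) and best.fun < 1e12
        flags = {}
        if "sigma" in self.free_names and values["sigma"] < SIGMA_FLOOR * 10:
            flags["sigma_at_floor"] = True
        return MixtureFitResults(
            model=self, params=values, nll=float(best.fun),
            converged=converged, n_restarts=n_used, flags=flags,
        )

    # -- simulation -------------------------------------------------------------

    def simulate(self, params, target_ids: Sequence[int],
                 rng: np.random.Generator) -> np.ndarray:
        """Responses (n, 2) for a sequence of true targets."""
        values = self.params_dict(params)
        W = self.weight_matrix(values)
        centers = self.layout.target_positions()
        index_of = {tid: i for i, tid in enumerate(self.layout.target_ids)}
        rows = np.array([index_of[t] for t in target_ids])
        comps = np.array([rng.choice(len(centers), p=W[r]) for r in rows])
        return centers[comps] + values["sigma"] * rng.standard_normal((len(rows), 2))


class SingleMultiCueModel(MixtureResponseModel):
    """The single/multi-cue stage-tree model (p1, p2 where applicable, p3)."""

    family = "smc"

    def __init__(self, trials, layout, fixed=None):
        self._PROB_PARAMS = ("p1", "p2", "p3") if layout.has_side_targets else ("p1", "p3")
        super().__init__(trials, layout, fixed=fixed)
        self._masks = _smc_masks(layout)

    def weight_matrix(self, values):
        return _smc_weight_matrix(self.layout, self._masks, values)

    def params_object(self, values):
        return SMCParams(p1=values["p1"], p2=values.get("p2"),
                         p3=values["p3"], sigma=values["sigma"])

    def start_params(self):
        lay = self.layout
        nt = self.d2.argmin(axis=1)
        true_lm = np.array([lay.targets[i].landmark_id for i in self.tidx])
        resp_lm = np.array([lay.targets[i].landmark_id for i in nt])
        lm_ok = resp_lm == true_lm
        p1 = float(np.clip(lm_ok.mean(), 0.05, 0.95))
        values = {"p1": p1, "sigma": self._sigma_start()}
        if lay.has_side_targets:
            true_rel = np.array([lay.targets[i].relation for i in self.tidx])
            resp_rel = np.array([lay.targets[i].relation for i in nt])
            rel_ok = lm_ok & (true_rel == resp_rel)
            denom = max(lm_ok.sum(), 1)
            values["p2"] = float(np.clip(rel_ok.sum() / denom, 0.05, 0.95))
            stage_ok = rel_ok
        else:
            stage_ok = lm_ok
        exact = stage_ok & (nt == self.tidx)
        denom = max(stage_ok.sum(), 1)
        values["p3"] = float(np.clip(exact.sum() / denom, 0.05, 0.95))
        values.update(self.fixed)
        return values


class CorrectOrGuessModel(MixtureResponseModel):
    """Correct with probability pc, otherwise a uniform guess."""

    family = "cog"
    _PROB_PARAMS = ("pc",)

    def weight_matrix(self, values):
        T = self.layout.n_targets
        pc = values["pc"]
        W = np.full((T, T), (1.0 - pc) / (T - 1))
        np.fill_diagonal(W, pc)
        return W

    def params_object(self, values):
        return CorrectOrGuessParams(pc=values["pc"], sigma=values["sigma"])

    def start_params(self):
        nt = self.d2.argmin(axis=1)
        pc = float(np.clip((nt == self.tidx).mean(), 0.05, 0.95))
        values = {"pc": pc, "sigma": self._sigma_start()}
        values.update(self.fixed)
        return values


class ExponentialDecayModel(MixtureResponseModel):
    """Component weights decaying as exp(-k d) with distance from the target."""

    family = "exp"
    _PROB_PARAMS = ()
    _POS_PARAMS = ("k", "sigma")

    def __init__(self, trials, layout, fixed=None):
        super().__init__(trials, layout, fixed=fixed)
        self._dist = pairwise_target_distances(layout)

    def weight_matrix(self, values):
        W = np.exp(-values["k"] * self._dist)
        return W / W.sum(axis=1, keepdims=True)

    def params_object(self, values):
        return ExpDecayParams(k=values["k"], sigma=values["sigma"])

    def start_params(self):
        values = {"k": 1.0, "sigma": self._sigma_start()}
        values.update(self.fixed)
        return values


class StructuredNoiseModel(MixtureResponseModel):
    """A structured-noise hierarchy model with stage probabilities q1..q3."""

    family = "structured"
    _PROB_PARAMS = ("q1", "q2", "q3")

    def __init__(self, trials, layout, hierarchy: Hierarchy, fixed=None):
        if layout.n_targets != 8:
            raise ValueError("structured-noise models require 8 targets")
        if set(hierarchy.leaves()) != set(layout.target_ids):
            raise ValueError("hierarchy leaves do not match layout targets")
        self.hierarchy = hierarchy
        super().__init__(trials, layout, fixed=fixed)
        # per-row index sets for fast weight construction
        idx = layout.target_index
        self._rows = []
        for t in layout.target_ids:
            _, og, _, op, sib = hierarchy.path(t)
            self._rows.append((
                idx(t),
                [idx(u) for pair in og for u in pair],
                [idx(u) for u in op],
                idx(sib),
            ))

    def weight_matrix(self, values):
        q1, q2, q3 = values["q1"], values["q2"], values["q3"]
        T = self.layout.n_targets
        W = np.zeros((T, T))
        for row, (ti, other4, other2, sib) in enumerate(self._rows):
            W[row, other4] = (1.0 - q1) / 4.0
            W[row, other2] = q1 * (1.0 - q2) / 2.0
            W[row, sib] = q1 * q2 * (1.0 - q3)
            W[row, ti] = q1 * q2 * q3
        return W

    def params_object(self, values):
        return {"q1": values["q1"], "q2": values["q2"], "q3": values["q3"],
                "sigma": values["sigma"], "hierarchy": self.hierarchy}

    def start_params(self):
        nt = self.d2.argmin(axis=1)
        ids = list(self.layout.target_ids)
        level1_ok = np.zeros(len(nt), bool)
        level2_ok = np.zeros(len(nt), bool)
        for i, (ti, other4, other2, sib) in enumerate(self._rows):
            sel = self.tidx == ti
            level1_ok[sel] = ~np.isin(nt[sel], other4)
            level2_ok[sel] = level1_ok[sel] & ~np.isin(nt[sel], other2)
        q1 = float(np.clip(level1_ok.mean(), 0.05, 0.95))
        q2 = float(np.clip(level2_ok.sum() / max(level1_ok.sum(), 1), 0.05, 0.95))
        exact = level2_ok & (nt == self.tidx)
        q3 = float(np.clip(exact.sum() / max(level2_ok.sum(), 1), 0.05, 0.95))
        values = {"q1": q1, "q2": q2, "q3": q3, "sigma": self._sigma_start()}
        values.update(self.fixed)
        return values


def _smc_masks(layout: Layout):
    T = layout.n_targets
    same_lm = np.zeros((T, T), bool)
    same_rel = np.zeros((T, T), bool)
    mirror = np.zeros(T, int)
    for i, t in enumerate(layout.targets):
        mirror[i] = layout.target_index(t.mirror_id)
        for j, u in enumerate(layout.targets):
            same_lm[i, j] = u.landmark_id == t.landmark_id
            same_rel[i, j] = u.relation == t.relation
    return same_lm, same_rel, mirror


def _smc_weight_matrix(layout: Layout, masks, values) -> np.ndarray:
    same_lm, same_rel, mirror = masks
    T = layout.n_targets
    p1, p3 = values["p1"], values["p3"]
    W = np.zeros((T, T))
    other = ~same_lm
    W[other] = ((1.0 - p1) / other.sum(axis=1))[:, None].repeat(T, 1)[other]
    rows = np.arange(T)
    if layout.has_side_targets:
        p2 = values["p2"]
        wrong_rel = same_lm & ~same_rel
        W[wrong_rel] = (p1 * (1.0 - p2) / wrong_rel.sum(axis=1))[:, None].repeat(T, 1)[wrong_rel]
        W[rows, mirror] = p1 * p2 * (1.0 - p3)
        W[rows, rows] = p1 * p2 * p3
    else:
        W[rows, mirror] = p1 * (1.0 - p3)
        W[rows, rows] = p1 * p3
    return W


FAMILIES = {
    "smc": SingleMultiCueModel,
    "cog": CorrectOrGuessModel,
    "exp": ExponentialDecayModel,
    "structured": StructuredNoiseModel,
}


def make_model(family: str, trials: pd.DataFrame, layout: Layout,
               hierarchy: Hierarchy | None = None,
               fixed: Mapping[str, float] | None = None) -> MixtureResponseModel:
    """Instantiate a model family by name."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; known: {sorted(FAMILIES)}")
    if family == "structured":
        if hierarchy is None:
            raise ValueError("structured family needs a hierarchy")
        return StructuredNoiseModel(trials, layout, hierarchy, fixed=fixed)
    return FAMILIES[family](trials, layout, fixed=fixed)


@dataclass
class MixtureFitResults:
    """Results of a maximum-likelihood fit.

    ``params`` holds natural-scale values (probabilities in [0,1], sigma in
    metres); ``nll`` is the training negative log likelihood.
    """

    model: MixtureResponseModel
    params: dict[str, float]
    nll: float
    converged: bool
    n_restarts: int
    flags: dict = field(default_factory=dict)

    @property
    def llf(self) -> float:
        return -self.nll

    def weights(self, true_target: int) -> np.ndarray:
        values = dict(self.params)
        W = self.model.weight_matrix(values)
        return W[self.model.layout.target_index(true_target)]

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} maximum-likelihood fit",
            f"  layout: {self.model.layout.name}   trials: {len(self.model.tidx)}",
            f"  NLL: {self.nll:.4f}   converged: {self.converged}"
            f"   restarts: {self.n_restarts}",
        ]
        if self.flags:
            lines.append(f"  flags: {self.flags}")
        lines.append("  parameters:")
        for name in self.model.param_names:
            fixed = " (fixed)" if name in self.model.fixed else ""
            lines.append(f"    {name:>6s} = {self.params[name]:.4f}{fixed}")
        return "\n".join(lines)
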