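"""Cyclic componentwise gradient boosting of the beta GAMLSS.

The model keeps two additive predictors, eta_mu (mean, logit link) and
eta_phi (precision, log link).  One boosting iteration performs two
half-steps: first the mean submodel is updated with phi held fixed, then
the precision submodel with mu held fixed.  Each half-step computes the
score vector (the negative gradient of the loss, i.e. the derivative of
the beta log-likelihood with respect to the active linear predictor),
fits every candidate base-learner to that vector by penalized least
squares, selects the learner with the smallest weighted residual sum of
squares — the standard L2 surrogate for the best likelihood improvement —
and adds a step-length-scaled fraction of its coefficient increment to
the accumulated coefficients.  Early stopping of the iteration count is
the model's regularization and variable-selection mechanism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import betadist
from .baselearners import BaseLearner
from .betadist import DistState, ProportionSample, make_state

__all__ = [
    "BoostConfig",
    "BoostedModel",
    "boost_fit",
    "selection_frequencies",
    "odds_factor",
]


@dataclass
class BoostConfig:
    """Knobs of the boosting loop.

    m_stop : number of iterations (each updates both submodels once).
    step_length : shrinkage factor nu applied to every coefficient
        increment; 0.1 is the framework convention.
    init : "ml" starts from maximum-likelihood intercept offsets
        (moment-matched mu and phi); "zero" starts both linear
        predictors at zero (mu = 0.5, phi = 1), the schematic textbook
        initialization.  Both reach the same path limit; zero init
        merely spends iterations on the intercepts.
    fixed_precision : restrict the precision submodel to its intercept,
        giving the classical fixed-dispersion beta regression.
    """

    m_stop: int = 1000
    step_length: float = 0.1
    init: str = "ml"
    fixed_precision: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_stop < 0 or not math.isfinite(self.m_stop):
            raise ValueError("m_stop must be a finite non-negative integer")
        if not 0.0 < self.step_length <= 1.0:
            raise ValueError("step_length must lie in (0, 1]")
        if self.init not in ("ml", "zero"):
            raise ValueError("init must be 'ml' or 'zero'")


@dataclass
class BoostedModel:
    """Fitted boosting state: offsets, learners with accumulated
    coefficients, and the per-half-step selection history."""

    offset_mu: float
    offset_phi: float
    learners_mu: list[BaseLearner]
    learners_phi: list[BaseLearner]
    history: list[tuple[int, str, str, float]]  # (iteration, submodel, label, negloglik)
    config: BoostConfig

    @property
    def m_stop(self) -> int:
        return self.config.m_stop

    def predict(self, data, what: str = "mu") -> np.ndarray:
        """Predict on new rows.

        ``what`` is one of ``eta_mu``, ``eta_phi``, ``mu``, ``phi`` or
        ``variance``.
        """
        n = len(data)
        if what in ("eta_mu", "mu", "variance"):
            eta_mu = np.full(n, self.offset_mu)
            for bl in self.learners_mu:
                if bl.selected:
                    eta_mu = eta_mu + bl.predict(data)
            if what == "eta_mu":
                return eta_mu
        if what in ("eta_phi", "phi", "variance"):
            eta_phi = np.full(n, self.offset_phi)
            for bl in self.learners_phi:
                if bl.selected:
                    eta_phi = eta_phi + bl.predict(data)
            if what == "eta_phi":
                return eta_phi
        if what == "mu":
            return make_state(eta_mu, np.zeros(n)).mu
        if what == "phi":
            return make_state(np.zeros(n), eta_phi).phi
        if what == "variance":
            st = make_state(eta_mu, eta_phi)
            return betadist.beta_variance(st.mu, st.phi)
        raise ValueError(f"unknown prediction target {what!r}")

    def loglik(self, y: np.ndarray, data) -> float:
        st = make_state(self.predict(data, "eta_mu"), self.predict(data, "eta_phi"))
        return betadist.beta_loglik(y, st)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "offset_mu": self.offset_mu,
            "offset_phi": self.offset_phi,
            "learners_mu": [bl.to_dict() for bl in self.learners_mu],
            "learners_phi": [bl.to_dict() for bl in self.learners_phi],
            "history": [list(h) for h in self.history],
            "config": {
                "m_stop": self.config.m_stop,
                "step_length": self.config.step_length,
                "init": self.config.init,
                "fixed_precision": self.config.fixed_precision,
                "seed": self.config.seed,
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedModel":
        return cls(
            offset_mu=d["offset_mu"],
            offset_phi=d["offset_phi"],
            learners_mu=[BaseLearner.from_dict(b) for b in d["learners_mu"]],
            learners_phi=[BaseLearner.from_dict(b) for b in d["learners_phi"]],
            history=[tuple(h) for h in d["history"]],
            config=BoostConfig(**d["config"]),
        )

    @classmethod
    def load(cls, path) -> "BoostedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _offsets(y: np.ndarray, weights: np.ndarray | None, init: str) -> tuple[float, float]:
    if init == "zero":
        return 0.0, 0.0
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    m = float(np.average(y, weights=w))
    v = float(np.average((y - m) ** 2, weights=w))
    m = min(max(m, 1e-6), 1.0 - 1e-6)
    phi0 = max(m * (1.0 - m) / max(v, 1e-12) - 1.0, 0.1)
    return float(betadist.logit(m)), float(np.log(phi0))


def _half_step(
    y: np.ndarray,
    state: DistState,
    learners: list[BaseLearner],
    score_fn,
    weights: np.ndarray | None,
    nu: float,
) -> tuple[BaseLearner, np.ndarray]:
    """Select and update the best learner for one submodel; returns the
    winner and its step-scaled fitted increment."""
    u = score_fn(y, state)
    w = weights
    best = None
    best_sse = np.inf
    best_inc = None
    best_fit = None
    for bl in learners:
        inc, fit = bl.fit_increment(u)
        resid = u - fit
        sse = float(np.dot(resid, resid) if w is None else np.dot(w, resid * resid))
        if sse < best_sse - 1e-12:  # ties broken by declaration order
            best, best_sse, best_inc, best_fit = bl, sse, inc, fit
    best.coef = best.coef + nu * best_inc
    return best, nu * best_fit


def boost_fit(
    sample: ProportionSample,
    learners_mu: list[BaseLearner],
    learners_phi: list[BaseLearner],
    cfg: BoostConfig,
    weights: np.ndarray | None = None,
    trace_callback=None,
) -> BoostedModel:
    """Run the cyclic boosting loop for cfg.m_stop iterations.

    ``weights`` are non-negative case weights (integer counts reproduce a
    bootstrap resample without physically replicating rows; zero-weight
    rows are held out entirely).  ``trace_callback(m, eta_mu, eta_phi)``
    is invoked after every completed iteration, which is how the
    cross-validation driver reads out-of-bag risk along a single path.
    """
    y = sample.values
    n = y.size
    if not learners_mu or not learners_phi:
        raise ValueError("each submodel needs at least one base-learner")
    for bl in learners_mu + learners_phi:
        if bl.design.shape[0] != n:
            raise ValueError(f"learner {bl.label} has {bl.design.shape[0]} rows, sample has {n}")
        bl.coef = np.zeros(bl.n_params)
        bl.prepare(weights)

    if cfg.fixed_precision:
        learners_phi_active = [bl for bl in learners_phi if bl.kind == "intercept"]
        if not learners_phi_active:
            raise ValueError("fixed_precision requires an intercept learner in the phi submodel")
    else:
        learners_phi_active = learners_phi

    off_mu, off_phi = _offsets(y, weights, cfg.init)
    eta_mu = np.full(n, off_mu)
    eta_phi = np.full(n, off_phi)
    state = make_state(eta_mu, eta_phi)
    w = None if weights is None else np.asarray(weights, dtype=float)
    nu = cfg.step_length
    history: list[tuple[int, str, str, float]] = []

    def negll(st: DistState) -> float:
        return -betadist.beta_loglik(y, st, w)

    for m in range(1, cfg.m_stop + 1):
        best, delta = _half_step(y, state, learners_mu, betadist.score_eta_mu, w, nu)
        eta_mu = eta_mu + delta
        state = make_state(eta_mu, eta_phi)
        loss = negll(state)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at iteration {m} after mean update by {best.label}"
            )
        history.append((m, "mu", best.label, loss))

        best, delta = _half_step(y, state, learners_phi_active, betadist.score_eta_phi, w, nu)
        eta_phi = eta_phi + delta
        state = make_state(eta_mu, eta_phi)
        loss = negll(state)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at iteration {m} after precision update by {best.label}"
            )
        history.append((m, "phi", best.label, loss))

        if trace_callback is not None:
            trace_callback(m, eta_mu, eta_phi)

    return BoostedModel(
        offset_mu=off_mu,
        offset_phi=off_phi,
        learners_mu=learners_mu,
        learners_phi=learners_phi,
        history=history,
        config=cfg,
    )


def selection_frequencies(models: list[BoostedModel]) -> "pd.DataFrame":
    """Fraction of models in which each base-learner carries a nonzero
    coefficient, split by submodel."""
    import pandas as pd

    vocab = None
    rows = {}
    for model in models:
        labels = tuple(
            (sub, bl.label, bl.kind)
            for sub, learners in (("mu", model.learners_mu), ("phi", model.learners_phi))
            for bl in learners
        )
        if vocab is None:
            vocab = labels
            for key in labels:
                rows[key] = 0
        elif labels != vocab:
            raise ValueError("models were fitted on different base-learner vocabularies")
        for (sub, lab, kind), bl in zip(
            labels,
            [b for b in model.learners_mu] + [b for b in model.learners_phi],
        ):
            rows[(sub, lab, kind)] += int(bl.selected)
    k = len(models)
    out = pd.DataFrame(
        [
            {
                "submodel": sub,
                "label": lab,
                "flavor": "linear" if kind in ("intercept", "linear", "categorical") else "nonlinear",
                "frequency": cnt / k,
            }
            for (sub, lab, kind), cnt in rows.items()
        ]
    )
    return out


def odds_factor(coef_delta: float) -> float:
    """Multiplicative change in the odds mu/(1-mu) per unit predictor
    change under the logit link: exp(coefficient)."""
    if not math.isfinite(coef_delta):
        raise ValueError("coefficient must be finite")
    return math.exp(coef_delta)
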