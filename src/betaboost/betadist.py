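"""Beta distribution in the (mu, phi) parameterization.

Beta regression models a response y in (0, 1) as Beta(a, b) with shape
parameters a = mu * phi and b = (1 - mu) * phi, so that E[y] = mu and
Var[y] = mu (1 - mu) / (1 + phi) — a scaled version of the binomial
variance.  The mean is linked to its linear predictor through the logit,
the precision phi through the log.  This module provides the density,
log-likelihood, link functions, the analytic score functions with respect
to both linear predictors (the working responses of the boosting
algorithm), beta sampling, and the standard boundary adjustment that pulls
exact 0/1 observations into the open interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "ProportionSample",
    "DistState",
    "MU_EPS",
    "PHI_MIN",
    "PHI_MAX",
    "logit",
    "inv_logit",
    "make_state",
    "beta_logpdf",
    "beta_loglik",
    "beta_variance",
    "score_eta_mu",
    "score_eta_phi",
    "boundary_adjust",
    "sample_beta",
]

# Guards applied inside link inversions: boosting can transiently push the
# linear predictors to extreme values, and the likelihood is undefined at
# mu in {0, 1} or phi <= 0.
MU_EPS = 1e-10
PHI_MIN = 1e-10
PHI_MAX = 1e10


@dataclass(frozen=True)
class ProportionSample:
    """A response vector strictly inside (0, 1).

    Attributes
    ----------
    values : ndarray
        Response values, each strictly in (0, 1).
    n_raw : int
        Number of original observations before any adjustment.
    adjusted : bool
        Whether the boundary adjustment ``(y (n - 1) + 0.5) / n`` was
        applied to the raw data.
    """

    values: np.ndarray
    n_raw: int
    adjusted: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a proportion sample needs at least 2 values")
        if np.any(v <= 0.0) or np.any(v >= 1.0):
            raise ValueError("proportion values must lie strictly in (0, 1)")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DistState:
    """Per-observation linked-parameter state (eta_mu, eta_phi, mu, phi)."""

    eta_mu: np.ndarray
    eta_phi: np.ndarray
    mu: np.ndarray
    phi: np.ndarray


def logit(p: np.ndarray | float) -> np.ndarray | float:
    return special.logit(p)


def inv_logit(eta: np.ndarray | float) -> np.ndarray | float:
    return special.expit(eta)


def make_state(eta_mu: np.ndarray, eta_phi: np.ndarray) -> DistState:
    """Invert the links, clipping mu into [MU_EPS, 1-MU_EPS] and phi into
    [PHI_MIN, PHI_MAX] so downstream likelihood evaluations stay finite."""
    eta_mu = np.asarray(eta_mu, dtype=float)
    eta_phi = np.asarray(eta_phi, dtype=float)
    mu = np.clip(special.expit(eta_mu), MU_EPS, 1.0 - MU_EPS)
    phi = np.clip(np.exp(np.clip(eta_phi, np.log(PHI_MIN), np.log(PHI_MAX))), PHI_MIN, PHI_MAX)
    return DistState(eta_mu=eta_mu, eta_phi=eta_phi, mu=mu, phi=phi)


def _check_domains(y, mu, phi) -> None:
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("y must lie strictly in (0, 1)")
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly in (0, 1)")
    if np.any(phi <= 0.0):
        raise ValueError("phi must be strictly positive")


def beta_logpdf(y, mu, phi):
    """Log-density of Beta(mu*phi, (1-mu)*phi) evaluated at y.

    log f = log G(phi) - log G(mu phi) - log G((1-mu) phi)
            + (mu phi - 1) log y + ((1-mu) phi - 1) log(1-y)
    """
    _check_domains(y, mu, phi)
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    if out.ndim == 0:
        return float(out)
    return out


def beta_loglik(sample_values, state: DistState, weights=None) -> float:
    """Total (optionally case-weighted) beta log-likelihood."""
    ll = beta_logpdf(sample_values, state.mu, state.phi)
    if weights is None:
        return float(np.sum(ll))
    return float(np.dot(np.asarray(weights, dtype=float), ll))


def beta_variance(mu, phi):
    """Conditional variance mu (1 - mu) / (1 + phi)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly in (0, 1)")
    if np.any(phi <= 0.0):
        raise ValueError("phi must be strictly positive")
    out = mu * (1.0 - mu) / (1.0 + phi)
    if out.ndim == 0:
        return float(out)
    return out


def _raise_if_nonfinite(v: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(v)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(f"non-finite {name} at observation index {idx}")


def score_eta_mu(y, state: DistState) -> np.ndarray:
    """Score of the log-likelihood with respect to eta_mu (logit link).

    d l / d eta_mu = phi * [log(y/(1-y)) - psi(mu phi) + psi((1-mu) phi)]
                     * mu * (1 - mu)

    This is the negative gradient of the loss, i.e. the working response
    the mean submodel's base-learners are fit to in each boosting step.
    """
    y = np.asarray(y, dtype=float)
    mu, phi = state.mu, state.phi
    s = phi * (np.log(y) - np.log1p(-y) - special.digamma(mu * phi) + special.digamma((1.0 - mu) * phi))
    s = s * mu * (1.0 - mu)
    _raise_if_nonfinite(s, "mean-submodel score")
    return s


def score_eta_phi(y, state: DistState) -> np.ndarray:
    """Score of the log-likelihood with respect to eta_phi (log link).

    d l / d eta_phi = phi * [psi(phi) - mu psi(mu phi) - (1-mu) psi((1-mu) phi)
                             + mu log y + (1-mu) log(1-y)]
    """
    y = np.asarray(y, dtype=float)
    mu, phi = state.mu, state.phi
    s = phi * (
        special.digamma(phi)
        - mu * special.digamma(mu * phi)
        - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
        + mu * np.log(y)
        + (1.0 - mu) * np.log1p(-y)
    )
    _raise_if_nonfinite(s, "precision-submodel score")
    return s


def boundary_adjust(y_raw, n: int | None = None, force: bool = False) -> ProportionSample:
    """Pull boundary proportions into the open interval.

    Maps every value through ``(y (n - 1) + 0.5) / n``.  The adjustment is
    applied to the whole vector whenever any raw value equals 0 or 1 (or
    unconditionally with ``force=True``); per-value adjustment would
    distort the ranks of the data.
    """
    y = np.asarray(y_raw, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need a vector of at least 2 raw values")
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError("raw values must lie in [0, 1]")
    if n is None:
        n = y.size
    has_boundary = bool(np.any(y == 0.0) | np.any(y == 1.0))
    if has_boundary or force:
        adj = (y * (n - 1) + 0.5) / n
        return ProportionSample(values=adj, n_raw=y.size, adjusted=True)
    return ProportionSample(values=y.copy(), n_raw=y.size, adjusted=False)


def sample_beta(state: DistState, seed=None) -> ProportionSample:
    """Draw independent Beta(mu_i phi_i, (1-mu_i) phi_i) observations."""
    rng = np.random.default_rng(seed)
    a = state.mu * state.phi
    b = (1.0 - state.mu) * state.phi
    y = stats.beta.rvs(a, b, random_state=rng)
    y = np.clip(y, MU_EPS, 1.0 - MU_EPS)
    return ProportionSample(values=np.atleast_1d(y), n_raw=int(np.size(y)), adjusted=False)
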