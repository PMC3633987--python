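"""Componentwise regression base-learners.

Each base-learner is a penalized least-squares smoother: a design matrix
B, a symmetric positive semi-definite penalty K and a smoothing weight
lambda calibrated so that the trace of the hat matrix
``B (B'B + lambda K)^(-1) B'`` equals a prescribed number of degrees of
freedom.  Holding every candidate learner at the same (small) df is what
keeps componentwise selection fair: a flexible P-spline cannot win over a
linear term merely because it has more free parameters.

Flavors
-------
- intercept: a single column of ones.
- linear: [1, x] with an optional ridge penalty (df-calibrated).
- categorical: one dummy column per level (no reference cell) with a
  ridge penalty, so rarely observed levels are shrunken toward zero.
- pspline: cubic B-spline basis on equidistant knots with a
  difference penalty on adjacent coefficients.
- decomposed P-spline: an unpenalized linear part plus a "centered"
  smooth part whose columns are orthogonal to {1, x}.  Selecting only the
  first gives a purely linear effect; the two parts together reproduce
  the full P-spline fit exactly.
- tensor-product surface: row-wise Kronecker product of two marginal
  B-spline bases with penalty K1 (x) I + I (x) K2, for spatial fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.interpolate import BSpline
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "SplineConfig",
    "BaseLearner",
    "build_intercept",
    "build_linear",
    "build_categorical",
    "build_pspline_basis",
    "build_pspline",
    "decompose_pspline",
    "build_tensor_surface",
    "calibrate_lambda",
    "hat_trace",
]


@dataclass(frozen=True)
class SplineConfig:
    """P-spline hyperparameters: knot count, spline degree, difference-penalty order."""

    n_inner_knots: int = 20
    degree: int = 3
    diff_order: int = 2

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("spline degree must be >= 1")
        if self.n_inner_knots < self.diff_order + 1:
            raise ValueError("need n_inner_knots >= diff_order + 1")


class DegeneratePredictorError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


def _knot_vector(lo: float, hi: float, cfg: SplineConfig) -> np.ndarray:
    if not hi > lo:
        raise DegeneratePredictorError("predictor has no spread; cannot place knots")
    breaks = np.linspace(lo, hi, cfg.n_inner_knots + 2)
    return np.concatenate([np.full(cfg.degree, lo), breaks, np.full(cfg.degree, hi)])


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = knots[degree], knots[-degree - 1]
    if np.any(x < lo) or np.any(x > hi):
        logger.warning(
            "evaluating spline basis outside the training range [%g, %g]; "
            "extrapolating the boundary polynomial", lo, hi,
        )
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _difference_penalty(p: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(p), n=order, axis=0)
    return D.T @ D


def build_pspline_basis(x: np.ndarray, cfg: SplineConfig) -> tuple[np.ndarray, np.ndarray]:
    """B-spline design on equidistant knots over [min(x), max(x)] and the
    difference penalty D'D of order ``cfg.diff_order``."""
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 2:
        raise DegeneratePredictorError("constant predictor; use an intercept learner")
    knots = _knot_vector(float(x.min()), float(x.max()), cfg)
    B = _bspline_design(x, knots, cfg.degree)
    K = _difference_penalty(B.shape[1], cfg.diff_order)
    return B, K


def _dr_eigenvalues(design: np.ndarray, penalty: np.ndarray) -> np.ndarray:
    """Demmler-Reinsch: eigenvalues s of R^-T K R^-1 with R'R = B'B, so that
    the effective df at smoothing weight lam is sum 1/(1 + lam * s)."""
    BtB = design.T @ design
    # tiny ridge keeps the Cholesky factor well defined when columns are
    # collinear on the observed data
    jitter = 1e-10 * max(np.trace(BtB) / BtB.shape[0], 1.0)
    R = sla.cholesky(BtB + jitter * np.eye(BtB.shape[0]), lower=False)
    Rinv = sla.solve_triangular(R, np.eye(R.shape[0]), lower=False)
    M = Rinv.T @ penalty @ Rinv
    s = sla.eigvalsh((M + M.T) / 2.0)
    return np.clip(s, 0.0, None)


def calibrate_lambda(design: np.ndarray, penalty: np.ndarray, df_target: float) -> float:
    """Smoothing weight lambda at which trace of the hat matrix equals df_target.

    Found by monotone root search on log(lambda); df(lambda) decreases from
    rank(design) at lambda=0 to the penalty null-space dimension as
    lambda -> infinity.
    """
    if df_target <= 0:
        raise CalibrationError("df_target must be positive")
    if not np.any(penalty):
        return 0.0
    s = _dr_eigenvalues(design, penalty)
    df_max = float(s.size)  # df at lambda = 0
    df_min = float(np.sum(s < 1e-12))  # penalty null-space dimension

    def df_at(loglam: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(loglam) * s)))

    if df_target >= df_max - 1e-8:
        return 0.0
    if df_target <= df_min + 1e-8:
        raise CalibrationError(
            f"df_target={df_target} unattainable; attainable range is "
            f"({df_min}, {df_max}]"
        )
    lo, hi = -40.0, 40.0
    loglam = brentq(lambda t: df_at(t) - df_target, lo, hi, xtol=1e-12, rtol=1e-14)
    lam = float(np.exp(loglam))
    # polish against the exact trace: the Demmler-Reinsch jitter can shift
    # the root by ~1e-6 df when the design is ill conditioned (tensor bases)
    if abs(hat_trace(design, penalty, lam) - df_target) > 1e-8:
        try:
            lam = brentq(
                lambda t: hat_trace(design, penalty, np.exp(t)) - df_target,
                loglam - 2.0, loglam + 2.0, xtol=1e-13, rtol=1e-15,
            )
            lam = float(np.exp(lam))
        except ValueError:
            pass  # bracket failed; keep the Demmler-Reinsch root
    return lam


def hat_trace(design: np.ndarray, penalty: np.ndarray, lam: float) -> float:
    """Trace of B (B'B + lam K)^-1 B', computed by direct solve."""
    BtB = design.T @ design
    A = BtB + lam * penalty
    H = sla.solve(A, BtB, assume_a="pos")
    return float(np.trace(H))


class BaseLearner:
    """A single candidate model component with accumulated coefficients.

    Parameters are frozen at construction; :meth:`prepare` factors the
    penalized normal equations for a given case-weight vector, after which
    :meth:`fit_increment` maps a working-residual vector to a coefficient
    increment and fitted values in two matrix products.
    """

    def __init__(
        self,
        label: str,
        kind: str,
        design: np.ndarray,
        penalty: np.ndarray,
        df_target: float,
        lam: float | None = None,
        predict_info: dict | None = None,
    ) -> None:
        self.label = label
        self.kind = kind
        self.design = np.asarray(design, dtype=float)
        self.penalty = np.asarray(penalty, dtype=float)
        self.df_target = float(df_target)
        if lam is None:
            lam = calibrate_lambda(self.design, self.penalty, df_target)
        self.lam = float(lam)
        self.predict_info = predict_info or {}
        self.coef = np.zeros(self.design.shape[1])
        self._solver: np.ndarray | None = None  # (p, n) map u -> coef increment

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    # -- fitting ---------------------------------------------------------
    def prepare(self, weights: np.ndarray | None = None) -> None:
        """Factor (B'WB + lam K)^-1 B'W for the given case weights."""
        B = self.design
        if weights is None:
            BtW = B.T
        else:
            BtW = B.T * np.asarray(weights, dtype=float)
        A = BtW @ B + self.lam * self.penalty
        try:
            c, low = sla.cho_factor(A)
            self._solver = sla.cho_solve((c, low), BtW)
        except sla.LinAlgError:
            ridge = 1e-8 * max(np.trace(A) / A.shape[0], 1.0)
            logger.warning("singular normal equations for %s; ridge-stabilizing", self.label)
            self._solver = sla.solve(A + ridge * np.eye(A.shape[0]), BtW)

    def fit_increment(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Penalized LS fit of a working-residual vector.

        Returns ``(coef_increment, fitted_values)`` without mutating the
        accumulated coefficients; the boosting engine applies the
        step-length-scaled update itself.
        """
        if self._solver is None:
            self.prepare(None)
        inc = self._solver @ u
        return inc, self.design @ inc

    def contribution(self) -> np.ndarray:
        """Training-data contribution of the accumulated coefficients."""
        return self.design @ self.coef

    @property
    def selected(self) -> bool:
        return bool(np.any(self.coef != 0.0))

    # -- prediction ------------------------------------------------------
    def design_for(self, data) -> np.ndarray:
        """Design matrix rows for new data (a DataFrame-like with named columns)."""
        info = self.predict_info
        kind = self.kind
        if kind == "intercept":
            n = len(data)
            return np.ones((n, 1))
        if kind == "linear":
            x = np.asarray(data[info["column"]], dtype=float)
            xs = (x - info["center"]) / info["scale"]
            return np.column_stack([np.ones_like(xs), xs])
        if kind == "categorical":
            z = np.asarray(data[info["column"]])
            levels = info["levels"]
            idx = {lv: j for j, lv in enumerate(levels)}
            X = np.zeros((len(z), len(levels)))
            for i, v in enumerate(z):
                j = idx.get(str(v))
                if j is None:
                    if info.get("unseen", "error") == "error":
                        raise ValueError(
                            f"unseen level {v!r} for categorical learner {self.label}"
                        )
                else:
                    X[i, j] = 1.0
            return X
        if kind == "pspline":
            x = np.asarray(data[info["column"]], dtype=float)
            return _bspline_design(x, np.asarray(info["knots"]), info["degree"])
        if kind == "pspline_centered":
            x = np.asarray(data[info["column"]], dtype=float)
            B = _bspline_design(x, np.asarray(info["knots"]), info["degree"])
            Z = B @ np.asarray(info["transform"])
            X = np.column_stack([np.ones_like(x), x])
            return Z - X @ np.asarray(info["projection"])
        if kind == "tensor":
            lon = np.asarray(data[info["columns"][0]], dtype=float)
            lat = np.asarray(data[info["columns"][1]], dtype=float)
            B1 = _bspline_design(lon, np.asarray(info["knots1"]), info["degree"])
            B2 = _bspline_design(lat, np.asarray(info["knots2"]), info["degree"])
            return _row_kronecker(B1, B2)
        raise ValueError(f"unknown learner kind {kind!r}")

    def predict(self, data) -> np.ndarray:
        return self.design_for(data) @ self.coef

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        info = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.predict_info.items()
        }
        return {
            "label": self.label,
            "kind": self.kind,
            "df_target": self.df_target,
            "lambda": self.lam,
            "predict_info": info,
            "coef": self.coef.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaseLearner":
        obj = cls.__new__(cls)
        obj.label = d["label"]
        obj.kind = d["kind"]
        obj.df_target = d["df_target"]
        obj.lam = d["lambda"]
        obj.predict_info = d["predict_info"]
        obj.coef = np.asarray(d["coef"], dtype=float)
        obj.design = None
        obj.penalty = None
        obj._solver = None
        return obj


def _row_kronecker(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    n = B1.shape[0]
    return np.einsum("ij,ik->ijk", B1, B2).reshape(n, B1.shape[1] * B2.shape[1])


# -- factories -----------------------------------------------------------

def build_intercept(n: int, label: str = "intercept") -> BaseLearner:
    design = np.ones((n, 1))
    return BaseLearner(label, "intercept", design, np.zeros((1, 1)), df_target=1.0, lam=0.0)


def build_linear(x: np.ndarray, name: str, df_target: float = 1.0) -> BaseLearner:
    """Linear learner on [1, x] (x standardized internally).

    With ``df_target >= 2`` the fit is plain least squares; smaller targets
    are reached by a ridge penalty on both coefficients.
    """
    x = np.asarray(x, dtype=float)
    scale = float(x.std())
    if scale == 0.0:
        raise DegeneratePredictorError(f"predictor {name!r} is constant")
    center = float(x.mean())
    xs = (x - center) / scale
    design = np.column_stack([np.ones_like(xs), xs])
    penalty = np.eye(2) if df_target < 2.0 else np.zeros((2, 2))
    return BaseLearner(
        f"linear({name})", "linear", design, penalty, df_target,
        predict_info={"column": name, "center": center, "scale": scale},
    )


def build_categorical(
    z, name: str, ridge_df: float = 1.0, unseen: str = "error"
) -> BaseLearner:
    """Dummy-coded factor learner: one column per level, ridge-shrunken.

    No reference cell is dropped; the ridge penalty both identifies the
    fit (jointly with the intercept offset) and shrinks sparse levels'
    means toward zero.
    """
    z = np.asarray([str(v) for v in np.asarray(z)])
    levels = sorted(set(z.tolist()))
    if len(levels) < 2:
        raise DegeneratePredictorError(f"factor {name!r} has fewer than 2 observed levels")
    design = (z[:, None] == np.asarray(levels)[None, :]).astype(float)
    penalty = np.eye(len(levels))
    if ridge_df >= len(levels):
        penalty = np.zeros((len(levels), len(levels)))
    return BaseLearner(
        f"factor({name})", "categorical", design, penalty, ridge_df,
        predict_info={"column": name, "levels": levels, "unseen": unseen},
    )


def build_pspline(
    x: np.ndarray, name: str, cfg: SplineConfig | None = None, df_target: float = 4.0
) -> BaseLearner:
    cfg = cfg or SplineConfig()
    x = np.asarray(x, dtype=float)
    B, K = build_pspline_basis(x, cfg)
    knots = _knot_vector(float(x.min()), float(x.max()), cfg)
    return BaseLearner(
        f"pspline({name})", "pspline", B, K, df_target,
        predict_info={"column": name, "knots": knots, "degree": cfg.degree},
    )


def decompose_pspline(
    x: np.ndarray,
    name: str,
    cfg: SplineConfig | None = None,
    df_smooth: float = 1.0,
) -> tuple[BaseLearner, BaseLearner]:
    """Split a P-spline into an unpenalized linear part and a centered smooth.

    The penalty's null space (polynomials up to degree diff_order - 1) is
    reproduced exactly by {1, x} for the default second-order penalty, so
    the basis is rotated into that null space plus a ridge-penalized
    complement, which is then residualized against [1, x].  Because the
    two parts are orthogonal, their separate fits of any working residual
    sum exactly to the full P-spline fit under the matched penalty.
    """
    cfg = cfg or SplineConfig()
    if cfg.diff_order != 2:
        raise ValueError("decomposition assumes the second-order difference penalty")
    x = np.asarray(x, dtype=float)
    B, K = build_pspline_basis(x, cfg)
    knots = _knot_vector(float(x.min()), float(x.max()), cfg)

    evals, evecs = sla.eigh((K + K.T) / 2.0)
    null = evals < 1e-10 * evals.max()
    U1 = evecs[:, ~null]
    lam1 = evals[~null]
    T = U1 / np.sqrt(lam1)  # p x (p - nullity); penalty becomes identity
    Z = B @ T
    X = np.column_stack([np.ones_like(x), x])
    C = sla.lstsq(X, Z)[0]  # projection coefficients onto {1, x}
    Zc = Z - X @ C

    linear = build_linear(x, name, df_target=2.0)
    smooth = BaseLearner(
        f"pspline_centered({name})", "pspline_centered", Zc,
        np.eye(Zc.shape[1]), df_smooth,
        predict_info={
            "column": name, "knots": knots, "degree": cfg.degree,
            "transform": T, "projection": C,
        },
    )
    return linear, smooth


def build_tensor_surface(
    lon: np.ndarray,
    lat: np.ndarray,
    names: tuple[str, str] = ("lon", "lat"),
    cfg: SplineConfig | None = None,
    df_target: float = 6.0,
) -> BaseLearner:
    """Bivariate tensor-product P-spline surface over two coordinates."""
    cfg = cfg or SplineConfig(n_inner_knots=8)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    for arr, nm in ((lon, names[0]), (lat, names[1])):
        if np.unique(arr).size < 2:
            raise DegeneratePredictorError(f"coordinate {nm!r} is constant")
    k1 = _knot_vector(float(lon.min()), float(lon.max()), cfg)
    k2 = _knot_vector(float(lat.min()), float(lat.max()), cfg)
    B1 = _bspline_design(lon, k1, cfg.degree)
    B2 = _bspline_design(lat, k2, cfg.degree)
    design = _row_kronecker(B1, B2)
    p1, p2 = B1.shape[1], B2.shape[1]
    K1 = _difference_penalty(p1, cfg.diff_order)
    K2 = _difference_penalty(p2, cfg.diff_order)
    penalty = np.kron(K1, np.eye(p2)) + np.kron(np.eye(p1), K2)
    return BaseLearner(
        f"tensor({names[0]},{names[1]})", "tensor", design, penalty, df_target,
        predict_info={"columns": list(names), "knots1": k1, "knots2": k2, "degree": cfg.degree},
    )
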