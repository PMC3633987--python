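"""Synthetic proportion-outcome datasets for a lake-survey-like design.

The default preset emulates the structure of a national lake assessment:
roughly a thousand sites, ~78 mixed-type predictors of which only a
handful are informative, a multi-level basin-climate region factor with
some sparse levels, planar site coordinates carrying a smooth spatial
residual field, and a beta-distributed response whose mean *and*
precision both depend on predictors.  Skewed (log-normally distributed)
predictors are emitted both raw and log-transformed, mirroring the usual
preprocessing of water-chemistry variables; the true effects act on the
log scale.

The generator returns the full ground truth (per-row linear predictors,
mu, phi, and the individual effect functions), so recovery of effect
shapes and of the active predictor set can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import betadist
from .betadist import make_state, sample_beta

__all__ = ["EffectSpec", "SyntheticSpec", "generate", "nla_like_spec", "recovery_report"]


# -- effect shape library ------------------------------------------------
# Shapes chosen to resemble the qualitative patterns typical of benthic
# macroinvertebrate responses: rapid sigmoidal decay with urbanization,
# an inverted-U in elevation, monotone declines with depth and nutrient
# load, and a U-shaped precision effect in chlorophyll-a.

def sigmoid_decay(x, amplitude, center, scale):
    return amplitude / (1.0 + np.exp((x - center) / scale))


def inverted_u(x, amplitude, center, width):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))


def u_shape(x, amplitude, center, half_range):
    return amplitude * (((x - center) / half_range) ** 2)


def linear_effect(x, slope, center=0.0, scale=1.0):
    return slope * (x - center) / scale


_SHAPES = {
    "sigmoid_decay": sigmoid_decay,
    "inverted_u": inverted_u,
    "u_shape": u_shape,
    "linear": linear_effect,
}


@dataclass(frozen=True)
class EffectSpec:
    """One true predictor effect: which column, which submodel (mu/phi),
    which shape from the library, and its shape parameters."""

    column: str
    submodel: str  # "mu" | "phi"
    shape: str
    params: tuple

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _SHAPES[self.shape](np.asarray(x, dtype=float), *self.params)


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for one synthetic dataset."""

    n: int = 994
    effects: tuple = ()
    n_noise: int = 68
    region_levels: int = 12
    region_effects: tuple = ()
    spatial: bool = True
    spatial_amplitude: float = 0.5
    intercept_mu: float = -1.1
    intercept_phi: float = 2.1
    contaminate_zeros: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 50:
            raise ValueError("n must be >= 50")
        for e in self.effects:
            if e.submodel not in ("mu", "phi"):
                raise ValueError(f"unknown submodel {e.submodel!r}")
        if self.region_effects and len(self.region_effects) != self.region_levels:
            raise ValueError("region_effects must have one entry per level")


def nla_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default lake-survey-like preset: 994 sites, 78 predictor
    columns (77 continuous + 1 region factor) plus two coordinates,
    ~10 informative terms."""
    effects = (
        EffectSpec("dev_land", "mu", "sigmoid_decay", (1.0, 0.25, 0.08)),
        EffectSpec("elevation", "mu", "inverted_u", (1.0, 0.5, 0.18)),
        EffectSpec("depth", "mu", "linear", (-0.5, 0.5, 0.29)),
        EffectSpec("log_nitrogen", "mu", "linear", (-0.5, 0.0, 1.0)),
        EffectSpec("conductivity", "mu", "linear", (0.4, 0.5, 0.29)),
        EffectSpec("log_chla", "phi", "u_shape", (1.0, 0.0, 2.0)),
        EffectSpec("turbidity", "phi", "linear", (-0.3, 0.5, 0.29)),
    )
    # fixed per-level region effects on the logit-mean scale, mean zero
    region_effects = (0.20, 0.17, 0.18, -0.20, -0.23, 0.10,
                      -0.10, 0.05, -0.05, 0.15, -0.15, -0.12)
    defaults = dict(effects=effects, region_effects=region_effects, seed=seed)
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def _spatial_field(lon: np.ndarray, lat: np.ndarray, amplitude: float) -> np.ndarray:
    """Fixed smooth bump mixture over the unit square (mean-centered below)."""
    f = (
        np.exp(-((lon - 0.25) ** 2 + (lat - 0.7) ** 2) / (2 * 0.15**2))
        - np.exp(-((lon - 0.75) ** 2 + (lat - 0.3) ** 2) / (2 * 0.2**2))
    )
    return amplitude * f


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Draw one dataset and its ground-truth record.

    Returns ``(df, truth)``; df columns are the response ``y``, the
    coordinates ``lon``/``lat``, the region factor and the continuous
    predictors.  ``truth`` holds the per-row eta/mu/phi vectors, each
    effect's centered contribution, and the active column sets.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    cols: dict[str, np.ndarray] = {}

    # named predictors the default effect library refers to
    cols["dev_land"] = rng.uniform(0, 1, n)
    cols["elevation"] = rng.uniform(0, 1, n)
    cols["depth"] = rng.uniform(0, 1, n)
    cols["conductivity"] = rng.uniform(0, 1, n)
    cols["turbidity"] = rng.uniform(0, 1, n)
    # skewed water-chemistry predictors: raw is log-normal, log is standard normal
    for nm in ("nitrogen", "chla"):
        z = rng.normal(0.0, 1.0, n)
        cols[f"log_{nm}"] = z
        cols[nm] = np.exp(z)
    for j in range(spec.n_noise):
        cols[f"noise{j + 1:02d}"] = rng.uniform(0, 1, n)

    # region factor with unbalanced counts (a few sparse levels)
    L = spec.region_levels
    probs = np.linspace(1.0, 0.05, L)
    probs /= probs.sum()
    region_idx = rng.choice(L, size=n, p=probs)
    region = np.array([f"R{k + 1:02d}" for k in region_idx])
    cols["region"] = region

    lon = rng.uniform(0, 1, n)
    lat = rng.uniform(0, 1, n)

    eta_mu = np.full(n, spec.intercept_mu)
    eta_phi = np.full(n, spec.intercept_phi)
    effect_contribs: dict[tuple[str, str], np.ndarray] = {}
    for eff in spec.effects:
        contrib = eff(cols[eff.column])
        contrib = contrib - contrib.mean()  # identified only up to constants
        effect_contribs[(eff.submodel, eff.column)] = contrib
        if eff.submodel == "mu":
            eta_mu = eta_mu + contrib
        else:
            eta_phi = eta_phi + contrib

    if spec.region_effects:
        reff = np.asarray(spec.region_effects, dtype=float)
        reff = reff - reff.mean()
        region_contrib = reff[region_idx]
        eta_mu = eta_mu + region_contrib
    else:
        region_contrib = np.zeros(n)

    if spec.spatial:
        sp = _spatial_field(lon, lat, spec.spatial_amplitude)
        sp = sp - sp.mean()
        eta_mu = eta_mu + sp
    else:
        sp = np.zeros(n)

    state = make_state(eta_mu, eta_phi)
    if np.any(state.phi <= 0):
        raise ValueError("spec implies non-positive precision")
    sample = sample_beta(state, seed=rng.integers(0, 2**31 - 1))
    y = sample.values.copy()
    if spec.contaminate_zeros > 0:
        idx = rng.choice(n, size=spec.contaminate_zeros, replace=False)
        y[idx] = 0.0

    df = pd.DataFrame({"y": y, "lon": lon, "lat": lat, **cols})
    truth = {
        "spec": spec,
        "eta_mu": eta_mu,
        "eta_phi": eta_phi,
        "mu": state.mu,
        "phi": state.phi,
        "effects": {k: v for k, v in effect_contribs.items()},
        "effect_specs": list(spec.effects),
        "region_contrib": region_contrib,
        "spatial_contrib": sp,
        "active_mu": sorted({e.column for e in spec.effects if e.submodel == "mu"}),
        "active_phi": sorted({e.column for e in spec.effects if e.submodel == "phi"}),
        "noise_columns": [f"noise{j + 1:02d}" for j in range(spec.n_noise)],
    }
    return df, truth


def _partial_prediction(model, submodel: str, column: str, grid: np.ndarray) -> np.ndarray:
    """Sum of the fitted contributions of every base-learner built on
    ``column`` in the given submodel, evaluated on a grid."""
    learners = model.learners_mu if submodel == "mu" else model.learners_phi
    data = pd.DataFrame({column: grid})
    out = np.zeros(grid.size)
    found = False
    for bl in learners:
        info = bl.predict_info
        if info.get("column") == column:
            found = True
            out = out + bl.predict(data)
    if not found:
        raise KeyError(f"model has no base-learner for {column!r} in {submodel}")
    return out


def recovery_report(truth: dict, model, data: pd.DataFrame, grid_size: int = 100,
                    q_lo: float = 0.05, q_hi: float = 0.95) -> dict:
    """Compare a fitted model against the generating truth.

    Per active continuous effect: RMSE between the centered true curve
    and the centered estimated partial function on an interior grid
    (between the q_lo and q_hi sample quantiles, where splines are well
    supported), together with the true curve's amplitude (max - min).
    Also reports selection sensitivity (fraction of active terms whose
    learners carry nonzero coefficients) and specificity (fraction of
    inert predictors left unselected) per submodel.
    """
    per_effect = {}
    for eff in truth["effect_specs"]:
        x = np.asarray(data[eff.column], dtype=float)
        lo, hi = np.quantile(x, [q_lo, q_hi])
        grid = np.linspace(lo, hi, grid_size)
        true_curve = eff(grid)
        true_curve = true_curve - true_curve.mean()
        est = _partial_prediction(model, eff.submodel, eff.column, grid)
        est = est - est.mean()
        rmse = float(np.sqrt(np.mean((true_curve - est) ** 2)))
        amplitude = float(true_curve.max() - true_curve.min())
        per_effect[(eff.submodel, eff.column)] = {
            "rmse": rmse,
            "amplitude": amplitude,
            "rel_rmse": rmse / amplitude if amplitude > 0 else np.nan,
        }

    def _selected_columns(learners):
        out = set()
        for bl in learners:
            if bl.selected:
                c = bl.predict_info.get("column")
                if c is not None:
                    out.add(c)
        return out

    sel_mu = _selected_columns(model.learners_mu)
    sel_phi = _selected_columns(model.learners_phi)
    report = {"per_effect": per_effect}
    for sub, sel in (("mu", sel_mu), ("phi", sel_phi)):
        active = set(truth[f"active_{sub}"])
        noise = set(truth["noise_columns"])
        tp = len(active & sel)
        report[f"sensitivity_{sub}"] = tp / len(active) if active else np.nan
        fp = len(noise & sel)
        report[f"specificity_{sub}"] = 1.0 - fp / len(noise) if noise else np.nan
    return report
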