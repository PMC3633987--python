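"""Dataset loading, analysis configuration and learner assembly.

The analysis configuration names the response column, the continuous and
categorical predictors and (optionally) a coordinate pair, plus the
knobs of the base-learners and the boosting loop.  ``load_dataset``
validates a CSV against it (complete-case handling: rows with missing
values in any used column are dropped, with a logged count), and
``make_learners`` assembles the base-learner vocabulary both submodels
share: an intercept, a decomposed linear + centered-smooth pair per
continuous predictor, a ridge-shrunken dummy block per factor, and a
tensor-product surface over the coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselearners import (
    SplineConfig,
    build_categorical,
    build_intercept,
    build_linear,
    build_tensor_surface,
    decompose_pspline,
)
from .boosting import BoostConfig

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "load_dataset", "make_learners"]


@dataclass
class AnalysisConfig:
    response: str = "y"
    continuous: list[str] = field(default_factory=list)
    categorical: list[str] = field(default_factory=list)
    coordinates: tuple[str, str] | None = None
    spline: SplineConfig = field(default_factory=SplineConfig)
    tensor_spline: SplineConfig = field(default_factory=lambda: SplineConfig(n_inner_knots=8))
    df_smooth: float = 1.0
    df_linear: float = 2.0
    df_categorical: float = 1.0
    df_tensor: float = 6.0
    smooth_terms: bool = True
    boost: BoostConfig = field(default_factory=BoostConfig)
    cv_folds: int = 25
    cv_grid_step: int = 10
    transform: str = "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        preds = set(self.continuous) | set(self.categorical)
        if self.response in preds:
            raise ValueError("response column cannot also be a predictor")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "spline" in raw:
            raw["spline"] = SplineConfig(**raw["spline"])
        if "tensor_spline" in raw:
            raw["tensor_spline"] = SplineConfig(**raw["tensor_spline"])
        if "boost" in raw:
            raw["boost"] = BoostConfig(**raw["boost"])
        if "coordinates" in raw and raw["coordinates"] is not None:
            raw["coordinates"] = tuple(raw["coordinates"])
        return cls(**raw)


def load_dataset(path, config: AnalysisConfig) -> tuple[pd.DataFrame, int, int]:
    """Read and validate a CSV; returns (table, n_before, n_after).

    Rows with a missing value in the response, any used predictor or a
    coordinate are dropped (complete-case analysis), with the drop count
    logged.
    """
    df = pd.read_csv(path)
    used = [config.response] + list(config.continuous) + list(config.categorical)
    if config.coordinates:
        used += list(config.coordinates)
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns in {path}: {missing_cols}")
    n_before = len(df)
    df = df.dropna(subset=used).reset_index(drop=True)
    n_after = len(df)
    if n_after < n_before:
        logger.info("dropped %d incomplete rows (%d -> %d)", n_before - n_after, n_before, n_after)
    if n_after < 10:
        raise ValueError("fewer than 10 complete rows after dropping missing values")
    y = pd.to_numeric(df[config.response], errors="raise").to_numpy()
    bad = np.flatnonzero((y < 0) | (y > 1))
    if bad.size:
        raise ValueError(f"response outside [0, 1] at row {int(bad[0])}")
    for c in config.continuous:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return df, n_before, n_after


def make_learners(df: pd.DataFrame, config: AnalysisConfig):
    """Build one base-learner vocabulary from the configured columns.

    Returns a zero-argument factory producing fresh (learners_mu,
    learners_phi) pairs; learners carry per-fit state, so every fit gets
    its own copies while sharing nothing mutable.
    """

    def build():
        learners = [build_intercept(len(df))]
        for c in config.continuous:
            x = df[c].to_numpy(dtype=float)
            if np.unique(x).size < 2:
                logger.warning("skipping constant predictor %s", c)
                continue
            if config.smooth_terms and np.unique(x).size > config.spline.n_inner_knots:
                lin, smooth = decompose_pspline(x, c, config.spline, df_smooth=config.df_smooth)
                learners += [lin, smooth]
            else:
                learners.append(build_linear(x, c, df_target=config.df_linear))
        for c in config.categorical:
            learners.append(build_categorical(df[c], c, ridge_df=config.df_categorical))
        if config.coordinates:
            cx, cy = config.coordinates
            learners.append(
                build_tensor_surface(
                    df[cx].to_numpy(dtype=float), df[cy].to_numpy(dtype=float),
                    names=(cx, cy), cfg=config.tensor_spline, df_target=config.df_tensor,
                )
            )
        return learners

    def factory():
        return build(), build()

    return factory
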