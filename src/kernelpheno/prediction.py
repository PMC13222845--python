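"""Random-Forest trait prediction protocol.

A fixed, deterministic configuration (100 trees, unrestricted depth, seed
42) is used across prediction tasks.  Training is two-step: an initial
forest is fitted on all samples, the samples with the largest absolute
prediction errors (top 5% by default) are dropped as gross outliers, and
the final forest is refitted on the remainder.  For vitreousness the raw
predictions are inverted (ŷ_inv = 1 - ŷ, because the driving endmember
abundances track mealy tissue) and the prediction batch is min–max scaled
into [0.1, 0.9] before class assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)


@dataclass
class RfConfig:
    """Shared Random-Forest protocol configuration."""

    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 42
    trim_fraction: float = 0.05
    cv_folds: int = 5
    y_min: float = 0.1
    y_max: float = 0.9

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if not self.y_min < self.y_max:
            raise ValueError("y_min must be < y_max")

    def make_forest(self) -> RandomForestRegressor:
        return RandomForestRegressor(n_estimators=self.n_trees,
                                     max_depth=self.max_depth,
                                     random_state=self.seed)


@dataclass
class TrimReport:
    dropped_ids: list[int]
    errors: np.ndarray = field(repr=False, default=None)


def train_rf_trimmed(X, y, cfg: RfConfig | None = None,
                     error_mode: str = "in_sample"):
    """Two-step trimmed training.

    Fits a first forest on all data, ranks samples by absolute prediction
    error (in-sample by default; ``error_mode="oob"`` uses out-of-bag
    predictions, which are less optimistic), drops the top
    ceil(trim_fraction * n), and fits the final forest on the remainder.

    Returns (fitted final model, TrimReport listing dropped sample indices).
    """
    cfg = cfg or RfConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 20:
        raise ValueError(f"need at least 20 samples, got {n}")

    k = math.ceil(cfg.trim_fraction * n)
    if n - k < 10:
        raise ValueError(f"trimming {k} of {n} samples would leave fewer than 10")

    model1 = cfg.make_forest()
    if error_mode == "oob":
        model1.set_params(oob_score=True, bootstrap=True)
    model1.fit(X, y)
    if k == 0:
        return model1, TrimReport([], np.abs(model1.predict(X) - y))
    if error_mode == "oob":
        pred = model1.oob_prediction_
    else:
        pred = model1.predict(X)
    errors = np.abs(pred - y)
    dropped = np.argsort(-errors, kind="stable")[:k]
    keep = np.setdiff1d(np.arange(n), dropped)
    final = cfg.make_forest()
    final.fit(X[keep], y[keep])
    log.info("train_rf_trimmed: dropped %d of %d samples", k, n)
    return final, TrimReport(sorted(int(i) for i in dropped), errors)


def predict_index(model, X, cfg: RfConfig | None = None,
                  invert: bool = False) -> np.ndarray:
    """Predict, optionally invert (1 - ŷ), and min–max scale the batch to
    [y_min, y_max].

    Scaling is per-prediction-batch: the batch minimum maps to y_min and the
    maximum to y_max.  A constant batch maps to the midpoint with a warning.
    """
    cfg = cfg or RfConfig()
    yhat = model.predict(np.asarray(X, dtype=float))
    if invert:
        yhat = 1.0 - yhat
    lo, hi = yhat.min(), yhat.max()
    if hi == lo:
        log.warning("predict_index: constant predictions mapped to midpoint")
        return np.full_like(yhat, (cfg.y_min + cfg.y_max) / 2)
    return cfg.y_min + (yhat - lo) * (cfg.y_max - cfg.y_min) / (hi - lo)


@dataclass
class CvResult:
    r2: float
    rmse: float
    fold_table: pd.DataFrame
    oof_predictions: np.ndarray = field(repr=False, default=None)

    @property
    def spearman(self) -> float:
        return self._spearman

    def __post_init__(self) -> None:
        self._spearman = float("nan")


def cross_validate(X, y, cfg: RfConfig | None = None) -> CvResult:
    """Seeded k-fold cross-validation of the forest.

    Out-of-fold predictions are pooled; R² = 1 - SS_res/SS_tot and RMSE are
    computed on the pooled vector (per-fold values are also tabulated).
    """
    cfg = cfg or RfConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < cfg.cv_folds:
        raise ValueError("need at least cv_folds samples")
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    oof = np.empty(n)
    rows = []
    for fold, (train, test) in enumerate(kf.split(X)):
        model = cfg.make_forest()
        model.fit(X[train], y[train])
        oof[test] = model.predict(X[test])
        resid = y[test] - oof[test]
        sst = float(((y[test] - y[test].mean()) ** 2).sum())
        rows.append({"fold": fold, "n_test": len(test),
                     "rmse": float(np.sqrt(np.mean(resid**2))),
                     "r2": 1 - float((resid**2).sum()) / sst if sst > 0 else float("nan")})
    resid = y - oof
    r2 = 1 - float((resid**2).sum()) / float(((y - y.mean()) ** 2).sum())
    rmse = float(np.sqrt(np.mean(resid**2)))
    result = CvResult(r2=r2, rmse=rmse, fold_table=pd.DataFrame(rows),
                      oof_predictions=oof)
    result._spearman = float(spearmanr(y, oof).statistic)
    return result


def index_to_class(v: float) -> str:
    """Class from a normalized index: v < 0.3 mealy, 0.3 <= v <= 0.7
    intermediate, v > 0.7 glassy."""
    if not np.isfinite(v):
        raise ValueError("index must be finite")
    if v < 0.3:
        return "mealy"
    if v <= 0.7:
        return "intermediate"
    return "glassy"
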