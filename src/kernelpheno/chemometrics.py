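"""Spectral chemometrics: SNV, the grain-coat color index, and PLSR with VIP.

The coat-color index contrasts a pigment-sensitive band (520 nm) against a
structure-dominated reference band (700 nm) on log10 reflectance.  In paired
mode it is built from the alkaline-treatment difference spectrum
ΔlogR(λ) = log R_pre(λ) - log R_post(λ):

    index = ΔlogR(700) - ΔlogR(520)

and in pre-treatment-only mode (no post spectrum available) it degrades to
log R_pre(700) - log R_pre(520).  White-coated kernels fall below ~0.175,
red-coated kernels above.  All logs are base 10 (configurable; changing the
base rescales the index and hence the threshold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

log = logging.getLogger(__name__)

DEFAULT_COLOR_THRESHOLD = 0.175
LOG_EPS = 1e-6


@dataclass
class SpectrumPair:
    """Reflectance spectra of a kernel before (and optionally after)
    alkaline treatment, on a shared wavelength axis."""

    pre: np.ndarray
    wavelengths: np.ndarray
    post: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.pre.shape != self.wavelengths.shape:
            raise ValueError("pre spectrum length != wavelength count")
        if self.post is not None:
            self.post = np.asarray(self.post, dtype=float)
            if self.post.shape != self.pre.shape:
                raise ValueError("post spectrum length != pre spectrum length")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: per-spectrum (x - mean) / sd (population sd).

    Accepts a single spectrum or a matrix of row spectra.  Constant spectra
    yield NaN sentinels with a warning.
    """
    x = np.asarray(spectrum, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        log.warning("snv: %d constant spectra set to NaN", int(const.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (x - mu) / sd
    out[const] = np.nan
    return out[0] if one_d else out


def color_index(pair: SpectrumPair, band_a_nm: float = 700.0,
                band_b_nm: float = 520.0, eps: float = LOG_EPS,
                base: float = 10.0) -> float:
    """Grain-coat color index on the nearest bands to 700 and 520 nm."""
    wl = pair.wavelengths
    ia = int(np.argmin(np.abs(wl - band_a_nm)))
    ib = int(np.argmin(np.abs(wl - band_b_nm)))

    def _log(v: float) -> float:
        return float(np.log(max(v, eps)) / np.log(base))

    if pair.post is not None:
        dlog_a = _log(pair.pre[ia]) - _log(pair.post[ia])
        dlog_b = _log(pair.pre[ib]) - _log(pair.post[ib])
        return dlog_a - dlog_b
    return _log(pair.pre[ia]) - _log(pair.pre[ib])


def classify_coat_color(index: float,
                        threshold: float = DEFAULT_COLOR_THRESHOLD) -> str:
    """'white' below the threshold, 'red' at or above it (right-closed)."""
    if not np.isfinite(index):
        raise ValueError("color index must be finite")
    if index == threshold:
        log.info("classify_coat_color: index exactly at threshold -> red")
    return "white" if index < threshold else "red"


# ---------------------------------------------------------------------------
# PLSR with VIP
# ---------------------------------------------------------------------------

@dataclass
class PlsrModel:
    """Fitted PLSR with CV curves and wavelength-importance scores."""

    n_lv: int
    weights: np.ndarray     # W (p x A)
    loadings: np.ndarray    # P (p x A)
    scores: np.ndarray      # T (n x A)
    y_loadings: np.ndarray  # q (A,)
    cv_r2: np.ndarray       # per-LV pooled CV R^2
    cv_rmse: np.ndarray     # per-LV pooled CV RMSE
    vip: np.ndarray         # per-wavelength VIP
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    estimator: PLSRegression

    @property
    def p(self) -> int:
        return self.weights.shape[0]


def _quantile_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded fold assignment stratified by response quantile.

    Samples are sorted by y; within each consecutive block of *folds*
    samples the fold labels are randomly permuted, so every fold spans the
    full response range.
    """
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    assignment = np.empty(len(y), dtype=int)
    for start in range(0, len(y), folds):
        block = order[start:start + folds]
        labels = rng.permutation(folds)[:len(block)]
        assignment[block] = labels
    return assignment


def _preprocess_fit(X: np.ndarray, apply_snv: bool):
    Z = snv(X) if apply_snv else X.astype(float)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Z - mu) / sd, mu, sd


def fit_plsr(X: np.ndarray, y: np.ndarray, max_lv: int = 10, folds: int = 10,
             seed: int = 0, apply_snv: bool = True) -> PlsrModel:
    """PLSR with the latent-variable count chosen by k-fold cross-validation.

    Preprocessing (optional SNV on row spectra, then column mean-centering
    and unit-variance scaling) is applied inside each CV split using
    training-fold statistics.  n_lv is the argmin of pooled CV RMSE (ties ->
    fewer LVs).  Factor extraction is NIPALS (scikit-learn PLSRegression).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= folds:
        raise ValueError("need more samples than CV folds")

    Z_all, _, _ = _preprocess_fit(X, apply_snv)
    rank = int(np.linalg.matrix_rank(Z_all))
    cap = max(1, min(max_lv, rank, n - max(2, n // folds) - 1))
    if cap < max_lv:
        log.warning("fit_plsr: max_lv %d capped at %d (rank/sample limit)",
                    max_lv, cap)

    assignment = _quantile_folds(y, folds, seed)
    cv_rmse = np.empty(cap)
    cv_r2 = np.empty(cap)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    for lv in range(1, cap + 1):
        pred = np.empty(n)
        for f in range(folds):
            test = assignment == f
            train = ~test
            Zt, mu, sd = _preprocess_fit(X[train], apply_snv)
            ym = y[train].mean()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls = PLSRegression(n_components=lv, scale=False)
                pls.fit(Zt, y[train] - ym)
            Zv = snv(X[test]) if apply_snv else X[test]
            pred[test] = pls.predict((Zv - mu) / sd).ravel() + ym
        resid = y - pred
        cv_rmse[lv - 1] = np.sqrt(np.mean(resid**2))
        cv_r2[lv - 1] = 1 - float((resid**2).sum()) / ss_tot
    n_lv = int(np.argmin(cv_rmse)) + 1  # argmin takes the first (fewest LVs)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = PLSRegression(n_components=n_lv, scale=False)
        Zf, mu, sd = _preprocess_fit(X, apply_snv)
        final.fit(Zf, y - y.mean())
    model = PlsrModel(
        n_lv=n_lv,
        weights=final.x_weights_,
        loadings=final.x_loadings_,
        scores=final.x_scores_,
        y_loadings=final.y_loadings_.ravel(),
        cv_r2=cv_r2, cv_rmse=cv_rmse,
        vip=np.empty(p),
        x_mean=mu, x_std=sd, y_mean=float(y.mean()),
        estimator=final,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsrModel) -> np.ndarray:
    """Variable Importance in Projection per wavelength.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), with
    SSY_a = q_a^2 t_a't_a the response variance captured by factor a (the
    sequential-deflation bookkeeping of NIPALS).  The identity
    mean(VIP^2) = 1 holds for every fitted model.
    """
    W = model.weights
    T = model.scores
    q = model.y_loadings
    p = W.shape[0]
    ssy = (q**2) * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total <= 0:
        log.warning("vip_scores: zero explained response variance")
        return np.full(p, np.nan)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
    return np.sqrt(p * ((W**2 / wnorm2) @ ssy) / total)
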