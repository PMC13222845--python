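"""Endmember extraction and linear spectral unmixing.

The linear mixing model treats each foreground pixel spectrum r as a
non-negative combination of endmember spectra E: r ≈ E a, a >= 0.  Endmembers
are extracted geometrically in a PCA-reduced score space by one of three
algorithms (PPI, N-FINDR, FIPPI); abundances are then estimated per pixel by
non-negative least squares and normalized post hoc to sum to one.

Reconstruction quality is summarized by the relative RMSE of the
*pre-normalization* least-squares fit (normalization changes the fit, so the
error must reflect the actual NNLS solution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls
from sklearn.decomposition import PCA

from .cube_io import SpectralCube
from .segmentation import ForegroundMask

log = logging.getLogger(__name__)

DEFAULT_N_SKEWERS = 10_000
DEFAULT_MIN_ANGLE_RAD = 0.05
DEFAULT_VAR_TARGET = 0.999


@dataclass
class EndmemberSet:
    """Extracted pure-component spectra, ordered by descending mean reflectance."""

    spectra: np.ndarray  # (n_em, bands)
    wavelengths: np.ndarray
    method: str
    seed: int | None = None
    labels: list[str] | None = None  # optional tissue-class tags

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.shape[1] != self.wavelengths.shape[0]:
            raise ValueError("endmember band count != wavelength count")
        if not np.isfinite(self.spectra).all():
            raise ValueError("endmember spectra must be finite")

    @property
    def n_em(self) -> int:
        return self.spectra.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths})
        for i, s in enumerate(self.spectra):
            name = self.labels[i] if self.labels else f"em{i + 1}"
            df[name] = s
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, method: str = "csv") -> "EndmemberSet":
        df = pd.read_csv(path)
        wl = df.iloc[:, 0].to_numpy(dtype=float)
        return cls(df.iloc[:, 1:].to_numpy(dtype=float).T, wl, method=method,
                   labels=list(df.columns[1:]))


@dataclass
class AbundanceMap:
    """Per-pixel endmember fractions on a foreground mask.

    On valid pixels the fractions are non-negative and sum to one (pixels
    whose NNLS solution is identically zero are flagged unclassifiable and
    left at zero).  Background pixels are zero.
    """

    fractions: np.ndarray  # (rows, cols, n_em)
    valid: ForegroundMask
    unclassifiable: np.ndarray | None = None  # bool grid

    @property
    def n_em(self) -> int:
        return self.fractions.shape[2]

    def pixel_matrix(self) -> np.ndarray:
        """Fractions of valid pixels as (n_valid, n_em)."""
        return self.fractions[self.valid.valid]


@dataclass
class UnmixDiagnostics:
    rrmse: float
    per_pixel_rmse: np.ndarray  # (rows, cols), NaN outside mask
    raw_abundances: np.ndarray = field(repr=False, default=None)  # (n_valid, n_em)


def spectral_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in radians between two spectra."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    denom = np.linalg.norm(u) * np.linalg.norm(v)
    if denom == 0:
        return np.pi / 2
    return float(np.arccos(np.clip(u @ v / denom, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

def pca_reduce(pixels: np.ndarray, var_target: float = DEFAULT_VAR_TARGET):
    """Center and project pixel spectra to the smallest dimension capturing
    *var_target* of the variance.

    Returns (scores, pca) where scores is (n_px, d) and pca the fitted
    :class:`sklearn.decomposition.PCA` basis.  Degenerate (zero-variance)
    input yields d = 1 with a warning.
    """
    pixels = np.asarray(pixels, dtype=float)
    n_px, bands = pixels.shape
    total_var = float(np.var(pixels, axis=0).sum())
    if total_var <= 1e-30:
        log.warning("pca_reduce: zero-variance input, returning d=1")
        pca = PCA(n_components=1).fit(pixels + np.random.default_rng(0).normal(
            scale=1e-12, size=pixels.shape))
        return np.zeros((n_px, 1)), pca
    pca = PCA(n_components=min(n_px - 1, bands)).fit(pixels)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, var_target) + 1)
    d = min(d, len(cum))
    scores = pca.transform(pixels)[:, :d]
    return scores, pca


# ---------------------------------------------------------------------------
# Endmember extraction
# ---------------------------------------------------------------------------

def _is_duplicate(a: np.ndarray, b: np.ndarray, min_angle_rad: float) -> bool:
    """Near-duplicate spectra: small spectral angle AND similar brightness.

    Spectral angle alone is intensity-invariant, so a dark flat background
    spectrum would wrongly collapse onto a bright featureless endosperm
    spectrum; the brightness ratio guard keeps distinct-intensity materials.
    """
    if spectral_angle(a, b) >= min_angle_rad:
        return False
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if max(na, nb) == 0:
        return True
    return min(na, nb) / max(na, nb) > 0.5


def _greedy_select(candidates: np.ndarray, counts: np.ndarray, raw_pixels: np.ndarray,
                   n_em: int, min_angle_rad: float,
                   scores: np.ndarray | None = None,
                   min_score_sep: float = 0.1) -> list[int]:
    """Greedy pick by descending purity count, skipping near-duplicates.

    Two dedup criteria: (i) spectral angle below *min_angle_rad* with
    similar brightness; (ii) when PCA scores are given, score-space distance
    below *min_score_sep* times the candidate-cloud diameter — pixel noise
    at a dark vertex can exceed the angle threshold while the pixels still
    sit on the same simplex vertex, which the score criterion catches.
    """
    order = candidates[np.argsort(-counts[candidates], kind="stable")]
    diam = 0.0
    if scores is not None and len(candidates) > 1:
        cs = scores[candidates]
        diam = float(np.sqrt(((cs[:, None] - cs[None, :]) ** 2).sum(-1).max()))
    chosen: list[int] = []
    for idx in order:
        spec = raw_pixels[idx]
        dup = any(_is_duplicate(spec, raw_pixels[j], min_angle_rad) for j in chosen)
        if not dup and scores is not None and diam > 0:
            dup = any(np.linalg.norm(scores[idx] - scores[j]) < min_score_sep * diam
                      for j in chosen)
        if not dup:
            chosen.append(int(idx))
        if len(chosen) == n_em:
            break
    if len(chosen) < n_em:
        log.warning("endmember selection: only %d of %d requested candidates "
                    "qualify", len(chosen), n_em)
    return chosen


def _finalize(spectra: np.ndarray, wavelengths: np.ndarray,
              method: str, seed: int | None) -> EndmemberSet:
    spectra = np.atleast_2d(spectra)
    order = np.argsort(-spectra.mean(axis=1), kind="stable")  # reproducible ids
    return EndmemberSet(spectra[order], wavelengths, method=method, seed=seed)


def _refine_vertex_means(raw_pixels: np.ndarray, scores: np.ndarray,
                         candidates: np.ndarray, chosen: list[int],
                         radius: float) -> np.ndarray:
    """Average the purity candidates clustered at each selected vertex.

    A selected endmember pixel carries the full per-band sensor noise; the
    other positive-purity candidates within the dedup radius sit on the same
    simplex vertex, so their mean is the same material with the noise
    suppressed.  Noiseless data are unaffected (co-located candidates are
    spectrally identical).
    """
    out = np.empty((len(chosen), raw_pixels.shape[1]))
    for k, idx in enumerate(chosen):
        d = np.linalg.norm(scores[candidates] - scores[idx], axis=1)
        members = candidates[d <= radius]
        out[k] = raw_pixels[members].mean(axis=0) if len(members) else raw_pixels[idx]
    return out


def extract_endmembers_ppi(scores: np.ndarray, raw_pixels: np.ndarray, n_em: int,
                           wavelengths: np.ndarray,
                           n_skewers: int = DEFAULT_N_SKEWERS, seed: int = 0,
                           both_extremes: bool = True,
                           min_angle_rad: float = DEFAULT_MIN_ANGLE_RAD,
                           refine: bool = True) -> EndmemberSet:
    """Pixel Purity Index endmember extraction.

    Scores are projected onto *n_skewers* random unit vectors; the extreme
    pixel(s) of each projection (min and max by default) accumulate purity
    counts.  Candidates with positive counts are ranked by count and greedily
    reduced to *n_em* endmembers subject to near-duplicate rejection.
    Returned spectra are original-space (not PCA-space) pixel spectra; with
    *refine* they are means over each vertex's co-located purity candidates
    (identical to the single pixel on noiseless data).
    """
    rng = np.random.default_rng(seed)
    d = scores.shape[1]
    skewers = rng.normal(size=(d, n_skewers))
    skewers /= np.linalg.norm(skewers, axis=0, keepdims=True)
    proj = scores @ skewers  # (n_px, n_skewers)
    counts = np.zeros(scores.shape[0], dtype=int)
    np.add.at(counts, np.argmax(proj, axis=0), 1)
    if both_extremes:
        np.add.at(counts, np.argmin(proj, axis=0), 1)
    candidates = np.flatnonzero(counts > 0)
    chosen = _greedy_select(candidates, counts, raw_pixels, n_em, min_angle_rad,
                            scores=scores)
    if refine and len(candidates) > 1:
        cs = scores[candidates]
        diam = float(np.sqrt(((cs[:, None] - cs[None, :]) ** 2).sum(-1).max()))
        spectra = _refine_vertex_means(raw_pixels, scores, candidates, chosen,
                                       0.05 * diam)
    else:
        spectra = raw_pixels[chosen]
    return _finalize(spectra, wavelengths, "PPI", seed)


def _simplex_volumes(vertices: np.ndarray, candidates: np.ndarray,
                     replace_idx: int) -> np.ndarray:
    """|det| of the simplex with vertex *replace_idx* swapped for each candidate.

    vertices: (n_em, d) with d = n_em - 1; candidates: (n_px, d).
    """
    n_em, d = vertices.shape
    mats = np.empty((candidates.shape[0], n_em, n_em))
    base = np.hstack([np.ones((n_em, 1)), vertices])  # rows are [1, v]
    mats[:] = base
    mats[:, replace_idx, 0] = 1.0
    mats[:, replace_idx, 1:] = candidates
    return np.abs(np.linalg.det(mats))


def extract_endmembers_nfindr(scores: np.ndarray, raw_pixels: np.ndarray, n_em: int,
                              wavelengths: np.ndarray, seed: int = 0,
                              max_iter: int = 50) -> EndmemberSet:
    """N-FINDR: maximize the volume of the (n_em-1)-simplex spanned by pixels.

    Works in the first n_em-1 PCA dimensions; starts from a random vertex set
    and swaps vertices for any pixel that increases the simplex volume until
    no improvement remains.
    """
    d_needed = n_em - 1
    if d_needed > scores.shape[1]:
        raise ValueError(f"n_em-1 = {d_needed} exceeds score dimension "
                         f"{scores.shape[1]}: simplex volume undefined")
    pts = scores[:, :d_needed]
    rng = np.random.default_rng(seed)
    n_px = pts.shape[0]
    current = rng.choice(n_px, size=n_em, replace=n_px < n_em)
    vertices = pts[current].copy()
    best_vol = np.abs(np.linalg.det(np.hstack([np.ones((n_em, 1)), vertices])))
    improved = True
    it = 0
    while improved and it < max_iter:
        improved = False
        it += 1
        for j in range(n_em):
            vols = _simplex_volumes(vertices, pts, j)
            k = int(np.argmax(vols))
            if vols[k] > best_vol * (1 + 1e-12) and vols[k] > best_vol:
                current[j] = k
                vertices[j] = pts[k]
                best_vol = vols[k]
                improved = True
    if best_vol <= 1e-30:
        log.warning("N-FINDR: zero simplex volume (degenerate data); "
                    "returning initial vertex set")
    return _finalize(raw_pixels[current], wavelengths, "NFINDR", seed)


def extract_endmembers_fippi(scores: np.ndarray, raw_pixels: np.ndarray, n_em: int,
                             wavelengths: np.ndarray, seed: int = 0,
                             n_skewers: int = 200, max_iter: int = 20,
                             min_angle_rad: float = DEFAULT_MIN_ANGLE_RAD,
                             refine: bool = True) -> EndmemberSet:
    """Fast Iterative PPI.

    Starts from a random skewer set; at each iteration the extreme pixels of
    the current projections become the next skewer directions (normalized
    scores), so skewers concentrate on the data's own extremes.  Stops when
    the extreme-pixel set stabilizes.  Output contract matches PPI.
    """
    rng = np.random.default_rng(seed)
    d = scores.shape[1]
    skewers = rng.normal(size=(d, n_skewers))
    skewers /= np.linalg.norm(skewers, axis=0, keepdims=True)
    extremes: set[int] = set()
    counts = np.zeros(scores.shape[0], dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        proj = scores @ skewers
        counts[:] = 0
        np.add.at(counts, np.argmax(proj, axis=0), 1)
        np.add.at(counts, np.argmin(proj, axis=0), 1)
        new_extremes = set(np.flatnonzero(counts > 0).tolist())
        if new_extremes == extremes:
            break
        extremes = new_extremes
        dirs = scores[sorted(extremes)].T  # (d, n_ext)
        norms = np.linalg.norm(dirs, axis=0)
        dirs = dirs[:, norms > 1e-12] / norms[norms > 1e-12]
        skewers = np.hstack([skewers, dirs]) if dirs.size else skewers
    log.info("FIPPI converged in %d iterations (%d extreme pixels)",
             n_iter, len(extremes))
    candidates = np.asarray(sorted(extremes), dtype=int)
    chosen = _greedy_select(candidates, counts, raw_pixels, n_em, min_angle_rad,
                            scores=scores)
    if refine and len(candidates) > 1:
        cs = scores[candidates]
        diam = float(np.sqrt(((cs[:, None] - cs[None, :]) ** 2).sum(-1).max()))
        spectra = _refine_vertex_means(raw_pixels, scores, candidates, chosen,
                                       0.05 * diam)
    else:
        spectra = raw_pixels[chosen]
    es = _finalize(spectra, wavelengths, "FIPPI", seed)
    es.n_iterations = n_iter
    return es


_EXTRACTORS = {
    "ppi": extract_endmembers_ppi,
    "nfindr": extract_endmembers_nfindr,
    "fippi": extract_endmembers_fippi,
}


def extract_endmembers(cube: SpectralCube, mask: ForegroundMask, n_em: int,
                       method: str = "ppi", seed: int = 0, **kwargs) -> EndmemberSet:
    """Convenience wrapper: PCA-reduce the valid pixels, then extract."""
    raw_pixels = cube.reflectance[mask.valid]
    method = method.lower()
    if method not in _EXTRACTORS:
        raise ValueError(f"unknown extraction method '{method}'")
    # Extraction runs in exactly n_em-1 PCA dimensions: a simplex with n_em
    # vertices spans n_em-1 dimensions, fewer dimensions can hide a
    # low-variance vertex (e.g. a dark background cluster) inside the hull,
    # and extra dimensions carry mostly noise that dilutes purity counts.
    scores, _ = pca_reduce(raw_pixels, var_target=1.0)
    scores = scores[:, :max(1, min(n_em - 1, scores.shape[1]))]
    return _EXTRACTORS[method](scores, raw_pixels, n_em, cube.wavelengths,
                               seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# NNLS unmixing
# ---------------------------------------------------------------------------

def nnls_unmix(cube: SpectralCube, mask: ForegroundMask,
               em: EndmemberSet) -> tuple[AbundanceMap, UnmixDiagnostics]:
    """Per-pixel non-negative least squares with post-hoc sum-to-one.

    For each valid pixel r solves min ||E a - r|| s.t. a >= 0, then
    normalizes a <- a / sum(a).  Pixels with sum(a) = 0 are flagged
    unclassifiable.  Diagnostics (rRMSE, per-pixel RMSE) are computed from
    the pre-normalization solutions.
    """
    if not np.array_equal(em.wavelengths, cube.wavelengths):
        raise ValueError("endmember wavelengths do not match cube")
    E = em.spectra.T  # (bands, n_em)
    if np.linalg.matrix_rank(E) < em.n_em:
        log.warning("nnls_unmix: endmember matrix is rank-deficient")
    pixels = cube.reflectance[mask.valid]  # (n_valid, bands)
    n_valid, bands = pixels.shape
    raw = np.zeros((n_valid, em.n_em))
    for i in range(n_valid):
        raw[i], _ = _nnls(E, pixels[i])

    recon = raw @ em.spectra
    resid = recon - pixels
    px_rmse = np.sqrt(np.mean(resid**2, axis=1))
    per_pixel = np.full(mask.valid.shape, np.nan)
    per_pixel[mask.valid] = px_rmse

    sums = raw.sum(axis=1)
    unclass = sums <= 0
    if unclass.any():
        log.warning("nnls_unmix: %d unclassifiable pixels (zero NNLS solution)",
                    int(unclass.sum()))
    norm = np.where(unclass, 1.0, sums)
    fractions_px = raw / norm[:, None]
    fractions_px[unclass] = 0.0
    fractions = np.zeros((*mask.valid.shape, em.n_em))
    fractions[mask.valid] = fractions_px
    unclass_grid = np.zeros(mask.valid.shape, dtype=bool)
    unclass_grid[mask.valid] = unclass

    rrmse = reconstruction_rrmse(cube, mask, em, raw)
    ab = AbundanceMap(fractions, mask, unclassifiable=unclass_grid)
    return ab, UnmixDiagnostics(rrmse=rrmse, per_pixel_rmse=per_pixel,
                                raw_abundances=raw)


def reconstruction_rrmse(cube: SpectralCube, mask: ForegroundMask,
                         em: EndmemberSet, raw_abundances: np.ndarray) -> float:
    """Relative reconstruction RMSE of the pre-normalization NNLS fit.

    rRMSE = sqrt(mean over valid pixels and bands of (R - E a)^2) / mean(R).
    """
    pixels = cube.reflectance[mask.valid]
    mean_r = float(pixels.mean())
    if mean_r == 0:
        raise ValueError("zero mean reflectance over valid pixels")
    recon = raw_abundances @ em.spectra
    return float(np.sqrt(np.mean((pixels - recon) ** 2)) / mean_r)


# ---------------------------------------------------------------------------
# Two-pass workflow
# ---------------------------------------------------------------------------

@dataclass
class TwoPassResult:
    em_global: EndmemberSet
    ab_global: AbundanceMap
    diag_global: UnmixDiagnostics
    background_em_ids: list[int]
    kernel_mask: ForegroundMask
    em_kernel: EndmemberSet
    ab_kernel: AbundanceMap
    diag_kernel: UnmixDiagnostics


def identify_background_endmembers(em: EndmemberSet,
                                   mean_factor: float = 0.5,
                                   max_cv: float = 0.15) -> list[int]:
    """Background/shadow endmembers: low-reflectance *flat* spectra.

    An endmember qualifies when its mean reflectance is below *mean_factor*
    times the median of all endmember means AND its coefficient of variation
    across bands is below *max_cv*.
    """
    means = em.spectra.mean(axis=1)
    scene_median = float(np.median(means))
    ids = []
    for i, s in enumerate(em.spectra):
        m = means[i]
        cv = float(np.std(s) / m) if m > 0 else np.inf
        if m < mean_factor * scene_median and cv < max_cv:
            ids.append(i)
    return ids


def two_pass_unmix(cube: SpectralCube, mask: ForegroundMask,
                   n_em_global: int = 10, n_em_kernel: int = 10,
                   method: str = "ppi", seed: int = 0,
                   bg_mean_factor: float = 0.5, bg_max_cv: float = 0.15,
                   bg_fraction_cut: float = 0.5, **kwargs) -> TwoPassResult:
    """Two-pass unmixing: global pass to purge background/shadow pixels,
    then a kernel-specific pass on the retained pixels.

    Pass 1 extracts *n_em_global* endmembers and unmixes the full foreground;
    endmembers with low, flat spectra are flagged as background and pixels
    whose summed background fraction exceeds *bg_fraction_cut* are removed.
    Pass 2 repeats extraction and unmixing on the cleaned mask.
    """
    em1 = extract_endmembers(cube, mask, n_em_global, method=method, seed=seed, **kwargs)
    ab1, diag1 = nnls_unmix(cube, mask, em1)
    bg_ids = identify_background_endmembers(em1, bg_mean_factor, bg_max_cv)
    if not bg_ids:
        log.warning("two_pass_unmix: no endmember qualifies as background; "
                    "keeping pass-1 mask unchanged")
        kernel_valid = mask.valid.copy()
    else:
        bg_frac = ab1.fractions[:, :, bg_ids].sum(axis=2)
        kernel_valid = mask.valid & ~(bg_frac > bg_fraction_cut)
    kernel_mask = ForegroundMask(kernel_valid)
    em2 = extract_endmembers(cube, kernel_mask, n_em_kernel, method=method,
                             seed=seed, **kwargs)
    ab2, diag2 = nnls_unmix(cube, kernel_mask, em2)
    return TwoPassResult(em1, ab1, diag1, bg_ids, kernel_mask, em2, ab2, diag2)
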