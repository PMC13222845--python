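"""Phantom generators: the verification substrate for the whole pipeline.

Three families of synthetic inputs with exact ground truth:

* hyperspectral kernel-scene phantoms — elliptical "kernels" on a grid over
  a dark platform, each pixel an exact linear mixture of three planted
  endosperm endmembers (mealy/intermediate/glassy) under a known abundance
  field, optionally with additive Gaussian noise at a stated SNR;
* cross-section shape phantoms — rectangles/ellipses with rectangular or
  triangular notches whose crease depth/width/area are known in closed form;
* trait tables — i.i.d. normal features with a known monotone
  feature->response mapping, optional gross outliers.

Every phantom is fully determined by (parameters, seed); defaults mirror
the acquisition conditions of the real study (12 x 8 kernels on a 512 x 512
frame, 425–974 nm axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import rotate as _rotate

from .cube_io import SpectralCube
from .geometry import CreaseRecord, composite_indices
from .segmentation import ForegroundMask, KernelLabelMap
from .unmixing import AbundanceMap, EndmemberSet, spectral_angle
from .vitreousness import CLASS_CODES, vitreousness_index

DEFAULT_WL_RANGE = (425.0, 974.0)
#: Planted mean-reflectance levels for (mealy, intermediate, glassy).
DEFAULT_LEVELS = (0.75, 0.45, 0.18)
DEFAULT_BACKGROUND_LEVEL = 0.03


@dataclass
class ScenePhantom:
    """A kernel scene with complete ground truth."""

    cube: SpectralCube
    true_endmembers: EndmemberSet
    true_abundance: AbundanceMap
    true_labels: KernelLabelMap
    true_class: np.ndarray          # per-pixel tissue codes (vitreousness.CLASS_CODES)
    true_v: np.ndarray              # per-kernel planted V
    pure_pixel_mask: np.ndarray     # bool grid: pixels planted with abundance 1
    background_spectrum: np.ndarray | None
    snr_db: float | None
    noise_sigma: float
    seed: int


@dataclass
class CreasePhantom:
    mask: np.ndarray
    truth: CreaseRecord


# ---------------------------------------------------------------------------
# Endmember spectra
# ---------------------------------------------------------------------------

def make_endmember_spectra(n_em: int = 3, bands: int = 200, seed: int = 0,
                           wl_range: tuple[float, float] = DEFAULT_WL_RANGE,
                           min_angle_rad: float = 0.1,
                           min_separation_rms: float = 0.04) -> EndmemberSet:
    """Smooth synthetic endosperm spectra with ordered mean reflectance.

    Each spectrum is a base level plus 2–4 Gaussian bumps on the wavelength
    axis.  Construction contracts (regenerated until all hold): mean
    reflectance ordered mealy > intermediate > glassy; pairwise spectral
    angles >= *min_angle_rad*; every spectrum keeps a per-band RMS distance
    of at least *min_separation_rms* reflectance units from the span of the
    others, so the planted simplex is well conditioned — no tissue class is
    a near-mixture of the other two, as distinct tissues are not.
    """
    if bands < 10:
        raise ValueError("need at least 10 bands")
    wl = np.linspace(*wl_range, bands)
    if n_em == 3:
        levels = np.array(DEFAULT_LEVELS)
        labels = ["mealy", "intermediate", "glassy"]
    else:
        levels = np.linspace(0.8, 0.15, n_em)
        labels = [f"em{i + 1}" for i in range(n_em)]
    # class-specific broad slopes emulate the real VNIR contrast: mealy
    # endosperm scatters strongly toward the NIR while glassy tissue stays
    # dark and comparatively flat — so the planted simplex differs in shape,
    # not just brightness, as real tissue spectra do
    if n_em == 3:
        slopes = np.array([0.30, 0.05, -0.08])
    else:
        slopes = np.linspace(0.3, -0.1, n_em)
    t = (wl - wl_range[0]) / (wl_range[1] - wl_range[0]) - 0.5
    rng = np.random.default_rng(seed)
    for _ in range(500):
        spectra = np.empty((n_em, bands))
        for i in range(n_em):
            s = levels[i] + slopes[i] * t
            for _ in range(rng.integers(2, 5)):
                center = rng.uniform(*wl_range)
                width = rng.uniform(30.0, 120.0)
                amp = rng.uniform(-0.12, 0.12)
                s = s + amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
            spectra[i] = np.clip(s, 0.01, None)
        means = spectra.mean(axis=1)
        ordered = np.all(np.diff(means) < 0)
        angles_ok = all(spectral_angle(spectra[i], spectra[j]) >= min_angle_rad
                        for i in range(n_em) for j in range(i + 1, n_em))
        if ordered and angles_ok and \
                _min_span_separation(spectra) >= min_separation_rms:
            return EndmemberSet(spectra, wl, method="synthetic", seed=seed,
                                labels=labels)
    raise RuntimeError("could not generate spectra meeting the contracts")


def _min_span_separation(spectra: np.ndarray) -> float:
    """Smallest per-band RMS distance of any spectrum from the others' span."""
    out = np.inf
    for i in range(spectra.shape[0]):
        others = np.delete(spectra, i, axis=0)
        coef, *_ = np.linalg.lstsq(others.T, spectra[i], rcond=None)
        resid = spectra[i] - others.T @ coef
        out = min(out, float(np.sqrt(np.mean(resid**2))))
    return out


# ---------------------------------------------------------------------------
# Kernel scenes
# ---------------------------------------------------------------------------

def _abundance_field(pattern: str, yy: np.ndarray, xx: np.ndarray,
                     a: float, b: float, pure_pixel_fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-pixel 3-endmember abundance rows for one elliptical kernel.

    yy/xx are pixel offsets from the kernel center, (a, b) the semi-axes.
    Rows sum to one exactly.
    """
    n = len(yy)
    ab = np.zeros((n, 3))
    if pattern == "pure_zones":
        # three vertical stripes, each pure one endmember
        zone = np.digitize(xx, [-a / 3, a / 3])
        for z in range(3):
            ab[zone == z, z] = 1.0
    elif pattern == "radial_gradient":
        # glassy core -> mealy rim, with pure plateaus at the core, at a
        # mid-radius annulus (intermediate) and at the rim so every
        # endmember has recoverable pure pixels
        r = np.sqrt((yy / b) ** 2 + (xx / a) ** 2)
        u = np.clip((r - 0.15) / 0.7, 0.0, 1.0)
        g = np.clip((0.45 - u) / 0.45, 0, 1)
        m = np.clip((u - 0.55) / 0.45, 0, 1)
        i = 1 - g - m
        ab[:, 0], ab[:, 1], ab[:, 2] = m, i, g
    elif pattern == "dirichlet":
        ab[:] = rng.dirichlet((0.5, 0.5, 0.5), size=n)
        n_pure = int(np.ceil(pure_pixel_fraction * n))
        idx = rng.choice(n, size=n_pure, replace=False)
        ab[idx] = 0.0
        ab[idx, np.arange(n_pure) % 3] = 1.0
    else:
        raise ValueError(f"unknown abundance pattern '{pattern}'")
    return ab


def make_kernel_scene(layout: tuple[int, int] = (12, 8),
                      image_shape: tuple[int, int] = (512, 512),
                      bands: int = 200,
                      abundance_pattern: str = "pure_zones",
                      pure_pixel_fraction: float = 0.2,
                      snr_db: float | None = None,
                      background: str = "zero",
                      kernel_fill: float = 0.72,
                      seed: int = 0,
                      endmembers: EndmemberSet | None = None) -> ScenePhantom:
    """Multi-kernel hyperspectral scene phantom with exact ground truth.

    Kernels are ellipses centered on a *layout* = (rows, cols) grid over
    *image_shape*, with semi-axes *kernel_fill*/2 of the cell pitch (so they
    never overlap).  Pixel spectra are exact mixtures of the planted
    endmembers under the chosen abundance pattern; additive Gaussian noise
    at *snr_db* is applied to foreground pixels only (the platform stays
    noiseless, matching a black low-reflectance background).  With
    ``background="dark_flat"`` the platform carries a flat dark spectrum
    instead of zeros, for exercising background-endmember removal.
    """
    n_rows, n_cols = layout
    H, W = image_shape
    pitch_r, pitch_c = H / n_rows, W / n_cols
    b_ax = kernel_fill * pitch_r / 2
    a_ax = kernel_fill * pitch_c / 2
    if 2 * b_ax > pitch_r or 2 * a_ax > pitch_c:
        raise ValueError("kernels would overlap for this layout/fill")

    em = endmembers or make_endmember_spectra(3, bands=bands, seed=seed)
    E = em.spectra  # (3, bands); order mealy, intermediate, glassy
    rng = np.random.default_rng(seed)

    fractions = np.zeros((H, W, 3))
    labels = np.zeros((H, W), dtype=int)
    valid = np.zeros((H, W), dtype=bool)
    rr, cc = np.mgrid[0:H, 0:W]
    kid = 0
    for i in range(n_rows):
        for j in range(n_cols):
            kid += 1
            cy = (i + 0.5) * pitch_r
            cx = (j + 0.5) * pitch_c
            inside = ((rr - cy) / b_ax) ** 2 + ((cc - cx) / a_ax) ** 2 <= 1.0
            yy = (rr[inside] - cy).astype(float)
            xx = (cc[inside] - cx).astype(float)
            ab = _abundance_field(abundance_pattern, yy, xx, a_ax, b_ax,
                                  pure_pixel_fraction, rng)
            fractions[inside] = ab
            labels[inside] = kid
            valid |= inside

    signal = fractions.reshape(-1, 3) @ E
    cube_data = signal.reshape(H, W, em.spectra.shape[1])

    background_spectrum = None
    if background == "dark_flat":
        background_spectrum = np.full(em.spectra.shape[1], DEFAULT_BACKGROUND_LEVEL)
        cube_data[~valid] = background_spectrum
    elif background != "zero":
        raise ValueError(f"unknown background mode '{background}'")

    sigma = 0.0
    if snr_db is not None:
        p_signal = float(np.mean(cube_data[valid] ** 2))
        sigma = float(np.sqrt(p_signal / 10 ** (snr_db / 10)))
        noise = rng.normal(scale=sigma, size=(int(valid.sum()), em.spectra.shape[1]))
        cube_data[valid] += noise

    wl = em.wavelengths
    cube = SpectralCube(cube_data, wl, source_id=f"phantom-seed{seed}")

    # per-pixel planted class: argmax of true abundances (ties -> lower id),
    # mapped through endmember order (mealy, intermediate, glassy)
    codes = np.full((H, W), -1, dtype=np.int8)
    order_codes = np.array([CLASS_CODES["mealy"], CLASS_CODES["intermediate"],
                            CLASS_CODES["glassy"]], dtype=np.int8)
    arg = np.argmax(fractions[valid], axis=1)
    codes_valid = order_codes[arg]
    codes[valid] = codes_valid

    true_v = np.empty(kid)
    for k in range(1, kid + 1):
        sel = labels == k
        c = codes[sel]
        true_v[k - 1] = vitreousness_index(
            int((c == CLASS_CODES["glassy"]).sum()),
            int((c == CLASS_CODES["intermediate"]).sum()),
            int((c == CLASS_CODES["mealy"]).sum()))

    pure = np.zeros((H, W), dtype=bool)
    pure[valid] = np.max(fractions[valid], axis=1) == 1.0

    return ScenePhantom(
        cube=cube,
        true_endmembers=em,
        true_abundance=AbundanceMap(fractions, ForegroundMask(valid)),
        true_labels=KernelLabelMap(labels, min_area_px=0),
        true_class=codes,
        true_v=true_v,
        pure_pixel_mask=pure,
        background_spectrum=background_spectrum,
        snr_db=snr_db,
        noise_sigma=sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Crease phantoms
# ---------------------------------------------------------------------------

def make_crease_phantom(outline: str = "rectangle", notch: str = "rectangular",
                        depth: int = 40, width: int = 20,
                        size: tuple[int, int] = (200, 100),
                        angle: float = 0.0, seed: int = 0) -> CreasePhantom:
    """Cross-section mask with an analytically known crease.

    *size* = (width_px, thickness_px) of the outline.  The notch is carved
    inward from the top edge, centered.  Analytic truth (before rotation,
    which leaves it invariant): rectangular notch CD = depth, CW = width,
    CA = depth*width; triangular notch CA = depth*width/2; no notch -> all
    zeros.  GT is the outline thickness, GW the outline width, SA the
    remaining mask area.
    """
    w_out, t_out = size
    pad = int(np.ceil(0.25 * max(size))) + 2
    H, W = t_out + 2 * pad, w_out + 2 * pad
    mask = np.zeros((H, W), dtype=bool)
    rr, cc = np.mgrid[0:H, 0:W]
    if outline == "rectangle":
        mask[pad:pad + t_out, pad:pad + w_out] = True
    elif outline == "ellipse":
        cy, cx = pad + t_out / 2, pad + w_out / 2
        mask = ((rr - cy) / (t_out / 2)) ** 2 + ((cc - cx) / (w_out / 2)) ** 2 <= 1.0
    else:
        raise ValueError(f"unknown outline '{outline}'")

    cd = cw = ca = 0.0
    if notch != "none":
        if not (depth < t_out and width < w_out):
            raise ValueError("notch must fit inside the outline")
        c0 = pad + (w_out - width) // 2
        top = rr - pad  # depth below the top edge of the outline
        if notch == "rectangular":
            cut = (top >= 0) & (top < depth) & (cc >= c0) & (cc < c0 + width)
            cd, cw, ca = float(depth), float(width), float(depth * width)
        elif notch == "triangular":
            # V-notch: full width at the edge narrowing linearly to the apex
            frac = 1.0 - top / depth
            half = (width / 2) * frac
            center = c0 + width / 2
            cut = (top >= 0) & (top < depth) & (np.abs(cc + 0.5 - center) < half)
            # 1-px spine down the center so the rasterized apex reaches the
            # full analytic depth
            cut |= (top >= 0) & (top < depth) & (cc == int(center - 0.5))
            cd, cw, ca = float(depth), float(width), float(depth * width / 2)
        else:
            raise ValueError(f"unknown notch '{notch}'")
        mask &= ~cut

    sa = float(mask.sum())
    gt, gw = float(t_out), float(w_out)
    dr, wr, cr, ci = composite_indices(cd, cw, ca, gt, sa, gw)
    if notch == "none":
        dr = wr = cr = ci = 0.0
    truth = CreaseRecord(cd=cd, cw=cw, ca=ca, gt=gt, sa=sa, gw_cs=gw,
                         dr=dr, wr=wr, cr=cr, ci=ci,
                         ca_over_sa=ca / sa if sa else 0.0)
    if angle:
        mask = _rotate(mask.astype(float), angle, resize=True, order=0) > 0.5
    return CreasePhantom(mask=mask, truth=truth)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

def make_trait_table(n: int = 300, n_features: int = 10, informative: int = 3,
                     noise_sd: float = 0.1, monotone: bool = True,
                     outliers: int = 0, seed: int = 0):
    """Feature table with a known feature->response mapping.

    Features are i.i.d. standard normal.  The response is a sum of smooth
    monotone transforms (x + 0.3 x^3) of the first *informative* features
    plus Gaussian noise (``monotone=False`` uses x^2 instead).  *outliers*
    samples receive gross response shifts of ±10 response-sd; their row ids
    are recorded in the returned metadata.

    Returns (TraitTable DataFrame, response Series, truth dict).
    """
    if informative > n_features:
        raise ValueError("informative must be <= n_features")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    f = (lambda x: x + 0.3 * x**3) if monotone else (lambda x: x**2)
    y = f(X[:, :informative]).sum(axis=1)
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=n)
    outlier_ids: list[int] = []
    if outliers > 0:
        outlier_ids = sorted(rng.choice(n, size=outliers, replace=False).tolist())
        shift = 10.0 * float(np.std(y))
        signs = rng.choice([-1.0, 1.0], size=outliers)
        y = y.copy()
        y[outlier_ids] += signs * shift
    table = pd.DataFrame(X, columns=[f"feature_{i + 1}" for i in range(n_features)])
    truth = {"informative": list(range(informative)),
             "outlier_ids": [int(i) for i in outlier_ids],
             "noise_sd": noise_sd, "monotone": monotone, "seed": seed}
    return table, pd.Series(y, name="response"), truth
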