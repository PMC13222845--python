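"""Hyperspectral cube I/O, radiometric calibration and spectral preprocessing.

Cubes are VNIR reflectance hypercubes (rows x cols x bands) with a
wavelength axis in nm.  On-disk format is ENVI: a text header (``.hdr``)
next to a raw binary file, in any of the three standard band interleaves
(BSQ, BIL, BIP).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

log = logging.getLogger(__name__)

#: ENVI numeric "data type" codes -> numpy dtypes (the subset we support).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}

#: Default wavelengths (nm) for RGB rendering.
DEFAULT_RGB_BANDS = (640.0, 550.0, 460.0)


@dataclass
class SpectralCube:
    """Calibrated reflectance hypercube with its wavelength axis.

    Attributes
    ----------
    reflectance : ndarray, shape (rows, cols, bands)
        Unitless reflectance.  Values above 1 (specular highlights) are
        allowed and passed through.
    wavelengths : ndarray, shape (bands,)
        Band centers in nm, strictly increasing.
    source_id : str
        Free-text provenance tag.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be rows x cols x bands")
        if self.reflectance.shape[2] != self.wavelengths.shape[0]:
            raise ValueError(
                f"band count {self.reflectance.shape[2]} != wavelength count "
                f"{self.wavelengths.shape[0]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]

    def nearest_band(self, nm: float) -> int:
        """Index of the band whose center is closest to *nm* (tie -> lower λ)."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass
class RgbImage:
    """8-bit 3-channel view, co-registered with its source cube."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    scale: float | None = None  # mm per pixel, unknown allowed
    band_indices: tuple[int, int, int] | None = field(default=None)


# ---------------------------------------------------------------------------
# ENVI header + raw binary I/O
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict of lowercase keys."""
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    # Collapse brace-delimited multi-line values onto one line.
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    header: dict = {}
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        header[key.strip().lower()] = val.strip()
    return header


def _header_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace(",", " ").split()]


def _find_data_file(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem, *(stem.with_suffix(ext) for ext in (".dat", ".raw", ".img", ".bsq", ".bil", ".bip"))):
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(f"no binary data file found next to {header_path}")


def read_envi_cube(header_path: str | Path) -> SpectralCube:
    """Read an ENVI cube (header + raw binary) into a :class:`SpectralCube`.

    Supports BSQ/BIL/BIP interleaves and float32/float64/uint16 samples.
    Raises a hard error when the header lacks wavelength metadata or when
    declared dimensions disagree with the wavelength list.
    """
    header_path = Path(header_path)
    header = _parse_envi_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "data type"):
        if key not in header:
            raise ValueError(f"ENVI header missing required key '{key}'")
    if "wavelength" not in header:
        raise ValueError("ENVI header missing required key 'wavelength'")

    samples = int(header["samples"])
    lines = int(header["lines"])
    bands = int(header["bands"])
    dtype_code = int(header["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(header.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = header.get("interleave", "bsq").lower()
    offset = int(header.get("header offset", "0"))

    wavelengths = np.asarray(_header_list(header["wavelength"]), dtype=float)
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )

    data_path = _find_data_file(header_path)
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if raw.size != samples * lines * bands:
        raise ValueError(
            f"data file holds {raw.size} samples, expected {samples * lines * bands}"
        )

    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave '{interleave}'")

    return SpectralCube(np.ascontiguousarray(cube), wavelengths, source_id=str(header_path))


def write_envi_cube(cube: SpectralCube, header_path: str | Path,
                    interleave: str = "bsq") -> Path:
    """Write a cube as ENVI float32 with the given interleave; returns data path."""
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".dat")
    arr = cube.reflectance.astype(np.float32)
    rows, cols, bands = arr.shape
    interleave = interleave.lower()
    if interleave == "bsq":
        flat = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = arr
    else:
        raise ValueError(f"unknown interleave '{interleave}'")
    flat.tofile(data_path)

    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return data_path


# ---------------------------------------------------------------------------
# Calibration and preprocessing
# ---------------------------------------------------------------------------

def calibrate_reflectance(raw: SpectralCube, white: SpectralCube,
                          dark: SpectralCube | None = None) -> SpectralCube:
    """Radiometric calibration against a white reference panel.

    R = (raw - dark) / (white - dark), with dark = 0 when absent.  The white
    (and dark) reference may be a full frame or a single 1x1 spectrum that is
    broadcast to all pixels.  Zero denominators produce non-finite pixels
    that downstream background filtering removes; they are not a hard error.
    """
    if not np.array_equal(raw.wavelengths, white.wavelengths):
        raise ValueError("raw and white wavelength axes differ")
    w = white.reflectance
    d = dark.reflectance if dark is not None else np.zeros((1, 1, raw.n_bands))
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.reflectance - d) / (w - d)
    return SpectralCube(refl, raw.wavelengths, source_id=raw.source_id)


def crop_bands(cube: SpectralCube, lo_nm: float, hi_nm: float) -> SpectralCube:
    """Retain exactly the bands with lo_nm <= λ <= hi_nm (inclusive)."""
    if not lo_nm < hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    keep = (cube.wavelengths >= lo_nm) & (cube.wavelengths <= hi_nm)
    if not keep.any():
        raise ValueError(f"no bands in [{lo_nm}, {hi_nm}] nm")
    return SpectralCube(cube.reflectance[:, :, keep], cube.wavelengths[keep],
                        source_id=cube.source_id)


def smooth_savitzky_golay(cube: SpectralCube, window: int = 11,
                          order: int = 2) -> SpectralCube:
    """Savitzky–Golay smoothing of every pixel spectrum along the band axis.

    The default window of 11 bands with a quadratic polynomial matches the
    acquisition protocol's smoothing scale (a nominal 10-band window rounded
    up to the nearest odd width, since the filter requires odd windows).
    Edges are handled by fitting the polynomial to the truncated terminal
    window rather than padding with invented data.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    if window >= cube.n_bands:
        raise ValueError(f"window {window} >= band count {cube.n_bands}")
    if window == 11 and order == 2:
        log.info("Savitzky–Golay defaults in use: window=11 (nearest odd above "
                 "the nominal 10), order=2")
    sm = savgol_filter(cube.reflectance, window, order, axis=2, mode="interp")
    return SpectralCube(sm, cube.wavelengths, source_id=cube.source_id)


def render_rgb(cube: SpectralCube,
               bands_nm: tuple[float, float, float] = DEFAULT_RGB_BANDS,
               scale: float | None = None) -> RgbImage:
    """Render a false-color RGB view from three wavelengths.

    Each channel uses the nearest available band (tie -> lower wavelength)
    and is min–max stretched to 0–255 independently; non-finite values are
    ignored by the stretch and rendered as 0.
    """
    for nm in bands_nm:
        if not (cube.wavelengths[0] <= nm <= cube.wavelengths[-1]):
            raise ValueError(f"{nm} nm outside cube range "
                             f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}]")
    idx = tuple(cube.nearest_band(nm) for nm in bands_nm)
    actual = tuple(cube.wavelengths[i] for i in idx)
    if any(abs(a - b) > 1e-9 for a, b in zip(actual, bands_nm)):
        log.info("render_rgb: requested %s nm, nearest bands %s nm", bands_nm, actual)
    out = np.zeros((*cube.reflectance.shape[:2], 3), dtype=np.uint8)
    for c, i in enumerate(idx):
        plane = cube.reflectance[:, :, i].astype(float)
        finite = np.isfinite(plane)
        if finite.any():
            lo = plane[finite].min()
            hi = plane[finite].max()
            if hi > lo:
                stretched = np.clip((plane - lo) / (hi - lo), 0, 1)
                out[:, :, c] = np.where(finite, np.round(stretched * 255), 0).astype(np.uint8)
    return RgbImage(out, scale=scale, band_indices=idx)
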