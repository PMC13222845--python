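"""Background filtering and per-kernel labelling on the acquisition grid.

Kernels are imaged on a dark, low-reflectance platform, so background and
shadow pixels carry near-zero spectral energy.  A pixel is foreground when
its spectrum is entirely finite and its summed absolute reflectance exceeds
a tolerance (default 1e-12).  Foreground blobs are then labelled and ordered
row-major to match the physical layout of kernels on the platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .cube_io import SpectralCube

log = logging.getLogger(__name__)

DEFAULT_ZERO_TOL = 1e-12
DEFAULT_MIN_AREA_PX = 50


@dataclass
class ForegroundMask:
    """Binary validity grid over the cube's spatial extent."""

    valid: np.ndarray  # (rows, cols) bool

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class KernelLabelMap:
    """Integer label grid: 0 = background, k >= 1 = kernel id (row-major order)."""

    labels: np.ndarray  # (rows, cols) int
    min_area_px: int

    @property
    def n_kernels(self) -> int:
        return int(self.labels.max())

    def table(self) -> pd.DataFrame:
        """Per-kernel (kernel_id, centroid_row, centroid_col, area_px)."""
        rows = []
        for rp in measure.regionprops(self.labels):
            rows.append({"kernel_id": rp.label,
                         "centroid_row": rp.centroid[0],
                         "centroid_col": rp.centroid[1],
                         "area_px": rp.area})
        return pd.DataFrame(rows).sort_values("kernel_id").reset_index(drop=True)


def background_mask(cube: SpectralCube, zero_tol: float = DEFAULT_ZERO_TOL) -> ForegroundMask:
    """Classify pixels as foreground vs background/shadow.

    Pixels with any NaN/Inf band are excluded; pixels whose summed absolute
    reflectance across all wavelengths is <= *zero_tol* are classified as
    background or shadow and removed.
    """
    refl = cube.reflectance
    finite = np.isfinite(refl).all(axis=2)
    energy = np.where(finite, np.abs(np.where(finite[..., None], refl, 0.0)).sum(axis=2), 0.0)
    valid = finite & (energy > zero_tol)
    if not valid.any():
        log.warning("background_mask: no foreground pixels found")
    return ForegroundMask(valid)


def _row_major_order(centroids: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """Order components top-to-bottom then left-to-right.

    Components are grouped into visual rows: sorted by centroid row, a new
    row starts when the centroid drops below the running row mean by more
    than half a typical blob height (median sqrt(area)).
    """
    row_tol = 0.5 * float(np.median(np.sqrt(areas))) if len(areas) else 0.0
    by_row = np.argsort(centroids[:, 0], kind="stable")
    order: list[int] = []
    group: list[int] = []
    group_mean = None
    for i in by_row:
        r = centroids[i, 0]
        if group and r - group_mean > max(row_tol, 1.0):
            group.sort(key=lambda j: centroids[j, 1])
            order.extend(group)
            group, group_mean = [], None
        group.append(i)
        group_mean = np.mean([centroids[j, 0] for j in group])
    group.sort(key=lambda j: centroids[j, 1])
    order.extend(group)
    return np.asarray(order, dtype=int)


def label_kernels(mask: ForegroundMask,
                  expected: tuple[int, int] | None = None,
                  min_area_px: int = DEFAULT_MIN_AREA_PX) -> KernelLabelMap:
    """Label connected foreground blobs as kernels, ordered row-major.

    8-connected components with area >= *min_area_px* are kept; ids are
    assigned by component centroid sorted top-to-bottom then left-to-right.
    When *expected* = (n_rows, n_cols) is given and the count differs, a
    warning reports the discrepancy.
    """
    lab = measure.label(mask.valid, connectivity=2)
    props = measure.regionprops(lab)
    keep = [rp for rp in props if rp.area >= min_area_px]
    out = np.zeros_like(lab)
    if not keep:
        log.warning("label_kernels: no components of area >= %d", min_area_px)
        return KernelLabelMap(out, min_area_px)
    centroids = np.array([rp.centroid for rp in keep])
    areas = np.array([rp.area for rp in keep], dtype=float)
    order = _row_major_order(centroids, areas)
    for new_id, i in enumerate(order, start=1):
        out[lab == keep[i].label] = new_id
    if expected is not None:
        n_expected = expected[0] * expected[1]
        if len(keep) != n_expected:
            log.warning("label_kernels: found %d kernels, expected %d (%dx%d grid)",
                        len(keep), n_expected, *expected)
    return KernelLabelMap(out, min_area_px)


def export_label_png(label_map: KernelLabelMap, path) -> None:
    """Write the label map as a 16-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, label_map.labels.astype(np.uint16))
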