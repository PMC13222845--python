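"""Grain morphometrics and convex-hull crease geometry.

External morphology (length, width, perimeter, area, aspect ratio,
circularity) is measured on intact-kernel masks.  Crease geometry is
measured on transverse cross-section masks: the wheat kernel's ventral
groove appears as the dominant deficit between the section and its convex
hull.  From that deficit region we measure

    CW  crease width  — length of the hull-boundary chord spanning the opening
    CD  crease depth  — max perpendicular distance from that chord to the
                        kernel boundary inside the groove
    CA  crease area   — deficit-region area
    GT  grain thickness       — mask extent perpendicular to the chord
    SA  cross-sectional area  — mask area
    GW  cross-section width   — mask extent parallel to the chord

and the derived indices DR = CD/GT, WR = CW/GW, CR = CA/(SA+CA) and the
composite crease index CI = (CD/GT) * (CW/GW^2).  CI carries units of
1/length as printed; it is implemented exactly as defined, with units
documented rather than silently corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_fill_holes, binary_opening
from scipy.spatial import ConvexHull
from skimage import measure, morphology
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)

#: Deficit components smaller than this (px) are rasterization slivers, not
#: creases; keeps convex digitized shapes at exactly zero crease measures.
DEFAULT_MIN_CREASE_AREA_PX = 16


@dataclass
class MorphologyRecord:
    """External grain morphology (units: px or mm when a scale is given)."""

    gl: float  # grain length (major axis)
    gw: float  # grain width (minor axis)
    gp: float  # grain perimeter
    ga: float  # grain area
    ar: float  # aspect ratio GL/GW
    gc: float  # circularity 4*pi*GA/GP^2


@dataclass
class CreaseRecord:
    """Cross-section crease geometry and derived indices."""

    cd: float
    cw: float
    ca: float
    gt: float
    sa: float
    gw_cs: float
    dr: float = field(default=0.0)
    wr: float = field(default=0.0)
    cr: float = field(default=0.0)
    ci: float = field(default=0.0)
    ca_over_sa: float = field(default=0.0)  # alternative area ratio, optional


def measure_external(mask: np.ndarray, scale: float | None = None) -> MorphologyRecord:
    """Morphology of a single connected kernel region.

    GL/GW are the equivalent-ellipse major/minor axis lengths (robust to
    rotation), GP the contour perimeter, GA the pixel area; AR = GL/GW and
    GC = 4*pi*GA/GP^2.  With *scale* (mm/px) lengths are in mm, areas mm^2.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    rp = max(props, key=lambda p: p.area)
    s = scale if scale is not None else 1.0
    gl = rp.axis_major_length * s
    gw = rp.axis_minor_length * s
    gp = rp.perimeter_crofton * s  # Crofton estimate: unbiased on smooth contours
    ga = rp.area * s * s
    return MorphologyRecord(gl=gl, gw=gw, gp=gp, ga=ga,
                            ar=gl / gw if gw > 0 else float("nan"),
                            gc=4 * np.pi * ga / gp**2 if gp > 0 else float("nan"))


def segment_cross_section(image: np.ndarray) -> np.ndarray:
    """Segment a kernel cross-section photographed against a dark background.

    Otsu threshold on grayscale, interior holes filled, largest connected
    component retained.
    """
    img = np.asarray(image)
    gray = rgb2gray(img) if img.ndim == 3 else img.astype(float)
    thr = threshold_otsu(gray)
    fg = gray > thr
    if not fg.any():
        raise ValueError("no foreground found in cross-section image")
    fg = binary_fill_holes(fg)
    lab = measure.label(fg, connectivity=2)
    if lab.max() > 1:
        log.warning("segment_cross_section: %d components, keeping largest", lab.max())
        areas = np.bincount(lab.ravel())[1:]
        fg = lab == (int(np.argmax(areas)) + 1)
    return fg


def _zero_record(sa: float, gt: float, gw_cs: float) -> CreaseRecord:
    return CreaseRecord(cd=0.0, cw=0.0, ca=0.0, gt=gt, sa=sa, gw_cs=gw_cs,
                        dr=0.0, wr=0.0, cr=0.0, ci=0.0, ca_over_sa=0.0)


def measure_crease(mask: np.ndarray, scale: float | None = None,
                   min_crease_area_px: int = DEFAULT_MIN_CREASE_AREA_PX) -> CreaseRecord:
    """Crease geometry of a cross-section mask via convex-hull deficit.

    The crease region is the largest connected component of hull-minus-mask.
    The opening chord lies on the hull facet the region breaches; CW is the
    span of the region's mouth along that facet and CD the maximum
    perpendicular distance from the facet line to mask pixels bordering the
    region.  Convex masks (deficit below *min_crease_area_px*) return all
    crease measures and ratios exactly zero.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    s = scale if scale is not None else 1.0
    sa_px = float(mask.sum())
    coords = np.argwhere(mask).astype(float)  # (n, 2) rows, cols

    hull_img = morphology.convex_hull_image(mask)
    deficit = hull_img & ~mask
    lab = measure.label(deficit, connectivity=2)
    if lab.max() == 0:
        ext = _extents(coords, np.array([0.0, 1.0]))
        return _zero_record(sa_px * s * s, ext[0] * s, ext[1] * s)
    areas = np.bincount(lab.ravel())[1:]
    crease_lab = int(np.argmax(areas)) + 1
    ca_px = float(areas[crease_lab - 1])
    if ca_px < min_crease_area_px:
        ext = _extents(coords, np.array([0.0, 1.0]))
        return _zero_record(sa_px * s * s, ext[0] * s, ext[1] * s)
    region = lab == crease_lab
    region_pts = np.argwhere(region).astype(float)

    # Oblique rasterized edges leave a 1-px zigzag sliver of deficit that
    # connects to the groove; a 3x3 morphological opening strips it before
    # the mouth is located (depth/area still use the full region).
    region_clean = binary_opening(region, structure=np.ones((3, 3)))
    mouth_pts = np.argwhere(region_clean).astype(float) if region_clean.any() \
        else region_pts

    # the opening chord lies on the hull facet the crease region breaches:
    # pick the facet with the most (cleaned) crease pixels near its line
    hull = ConvexHull(coords)
    eq = hull.equations  # (n_facets, 3): a*row + b*col + c <= 0 inside
    dists = np.abs(mouth_pts @ eq[:, :2].T + eq[:, 2])  # (n_pts, n_facets)
    near = dists <= 1.5
    facet = int(np.argmax(near.sum(axis=0)))
    opening = mouth_pts[near[:, facet]]
    if len(opening) == 0:
        # groove sealed off from the hull boundary at pixel resolution
        opening = mouth_pts
    a_f, b_f = eq[facet, :2]
    u = np.array([-b_f, a_f])  # facet direction (unit: equations are normalized)

    # chord endpoints = extreme opening pixels along the facet direction
    proj = opening @ u
    p_lo = opening[int(np.argmin(proj))]
    p_hi = opening[int(np.argmax(proj))]
    cw_px = float(np.linalg.norm(p_hi - p_lo) + 1)
    chord = p_hi - p_lo
    u = chord / np.linalg.norm(chord) if np.linalg.norm(chord) > 0 else u
    n = np.array([-u[1], u[0]])

    # depth measured from the chord line to the mask boundary inside the
    # groove: mask pixels adjacent to the crease region
    rim = binary_dilation(region, structure=np.ones((3, 3))) & mask
    rim_pts = np.argwhere(rim).astype(float)
    depth_pts = rim_pts if len(rim_pts) else region_pts
    cd_px = float(np.max(np.abs((depth_pts - p_lo) @ n)))

    gt_px = _extents(coords, u)[0]
    gw_px = _extents(coords, u)[1]

    cd, cw, ca = cd_px * s, cw_px * s, ca_px * s * s
    gt, sa, gw_cs = gt_px * s, sa_px * s * s, gw_px * s
    dr, wr, cr, ci = composite_indices(cd, cw, ca, gt, sa, gw_cs)
    return CreaseRecord(cd=cd, cw=cw, ca=ca, gt=gt, sa=sa, gw_cs=gw_cs,
                        dr=dr, wr=wr, cr=cr, ci=ci,
                        ca_over_sa=ca / sa if sa > 0 else 0.0)


def _extents(coords: np.ndarray, u: np.ndarray) -> tuple[float, float]:
    """Mask extent (max-min+1 px) perpendicular and parallel to direction u."""
    n = np.array([-u[1], u[0]])
    perp = coords @ n
    para = coords @ u
    return float(perp.max() - perp.min() + 1), float(para.max() - para.min() + 1)


def composite_indices(cd: float, cw: float, ca: float, gt: float,
                      sa: float, gw_cs: float) -> tuple[float, float, float, float]:
    """Derived crease indices (DR, WR, CR, CI).

    DR = CD/GT, WR = CW/GW, CR = CA/(SA+CA), CI = (CD/GT)*(CW/GW^2).
    Zero denominators yield NaN sentinels.
    """
    nan = float("nan")
    dr = cd / gt if gt > 0 else nan
    wr = cw / gw_cs if gw_cs > 0 else nan
    cr = ca / (sa + ca) if (sa + ca) > 0 else nan
    ci = (cd / gt) * (cw / gw_cs**2) if gt > 0 and gw_cs > 0 else nan
    return dr, wr, cr, ci


def crease_table(records: dict[str, CreaseRecord]) -> pd.DataFrame:
    rows = []
    for name, r in records.items():
        rows.append({"id": name, "CD": r.cd, "CW": r.cw, "CA": r.ca, "GT": r.gt,
                     "SA": r.sa, "GW_cs": r.gw_cs, "DR": r.dr, "WR": r.wr,
                     "CR": r.cr, "CI": r.ci, "CA_over_SA": r.ca_over_sa})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trait-table statistics
# ---------------------------------------------------------------------------

def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each numeric column: Z = (x - mean) / sd (population sd).

    Missing values are ignored when computing the moments and preserved in
    the output; constant columns become all-zero with a warning.
    """
    out = table.copy()
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        x = table[col].astype(float)
        mu = x.mean(skipna=True)
        sd = x.std(ddof=0, skipna=True)
        if sd == 0 or not np.isfinite(sd):
            log.warning("zscore_table: column '%s' is constant, set to zeros", col)
            out[col] = np.where(x.notna(), 0.0, np.nan)
        else:
            out[col] = (x - mu) / sd
    return out


def coefficient_of_variation(column) -> float:
    """CV in percent: 100 * sd / mean, population sd; NaN when mean = 0."""
    x = pd.Series(column).astype(float)
    mu = x.mean(skipna=True)
    if mu == 0 or not np.isfinite(mu):
        return float("nan")
    return float(100.0 * x.std(ddof=0, skipna=True) / mu)
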