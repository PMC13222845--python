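"""Tissue-class assignment, pixel classification and the vitreousness index.

Wheat endosperm pixels fall into three spectral tissue classes: mealy areas
have the highest reflectance (air-filled micropores scatter light), glassy
regions the lowest, with intermediate tissue between.  The kernel-level
vitreousness index weights the intermediate class by one half:

    V = (N_g + 0.5 * N_i) / N_total,  V in [0, 1]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import KernelLabelMap
from .unmixing import AbundanceMap, EndmemberSet

log = logging.getLogger(__name__)

#: Canonical class order used throughout (confusion matrices, exports).
TISSUE_CLASSES = ("mealy", "intermediate", "glassy")
ENDOSPERM_CLASSES = frozenset(TISSUE_CLASSES)

#: Integer codes in the class grid produced by :func:`classify_pixels`.
CODE_BACKGROUND = -1
CODE_UNCLASSIFIED = 0
CLASS_CODES = {"glassy": 1, "intermediate": 2, "mealy": 3}
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class TissueAssignment:
    """Mapping from endmember id to tissue class.

    Every endmember maps exactly once to one of
    {glassy, intermediate, mealy, other}.
    """

    mapping: dict[int, str]
    mode: str  # "auto" | "manual"

    def __post_init__(self) -> None:
        allowed = ENDOSPERM_CLASSES | {"other"}
        for em_id, cls in self.mapping.items():
            if cls not in allowed:
                raise ValueError(f"endmember {em_id}: unknown class '{cls}'")

    def ids_for(self, cls: str) -> list[int]:
        return [i for i, c in self.mapping.items() if c == cls]


@dataclass
class KernelRecord:
    """Per-kernel class counts and vitreousness index."""

    kernel_id: int
    n_glassy: int
    n_intermediate: int
    n_mealy: int
    n_total: int
    v: float
    cultivar: str = ""


def assign_tissue_classes(em: EndmemberSet, ab: AbundanceMap,
                          kernel_mask: np.ndarray | None = None,
                          manual: dict[int, str] | None = None) -> TissueAssignment:
    """Map endmembers to tissue classes.

    With *manual* given, it is used verbatim (unmapped endmembers default to
    "other").  Otherwise, endmembers whose abundance concentrates inside
    kernels (mean in-kernel fraction > mean out-of-kernel fraction, judged
    against *kernel_mask* when provided) are ranked by mean spectrum
    reflectance: highest -> mealy, lowest -> glassy, the middle-ranked one ->
    intermediate; everything else -> other.  Ties in mean reflectance break
    toward the lower endmember id.
    """
    if manual is not None:
        mapping = {i: manual.get(i, "other") for i in range(em.n_em)}
        return TissueAssignment(mapping, mode="manual")

    valid = ab.valid.valid
    if kernel_mask is None:
        in_kernel_ids = list(range(em.n_em))
    else:
        inside = valid & kernel_mask
        outside = valid & ~kernel_mask
        in_kernel_ids = []
        for i in range(em.n_em):
            mean_in = ab.fractions[:, :, i][inside].mean() if inside.any() else 0.0
            mean_out = ab.fractions[:, :, i][outside].mean() if outside.any() else -np.inf
            if mean_in > mean_out:
                in_kernel_ids.append(i)
    if len(in_kernel_ids) < 3:
        raise ValueError(
            f"only {len(in_kernel_ids)} in-kernel endmembers; automatic tissue "
            "assignment needs 3 — provide a manual mapping")

    means = em.spectra.mean(axis=1)
    # sort by (mean reflectance, then lower id first) so ties go to lower ids
    ranked = sorted(in_kernel_ids, key=lambda i: (means[i], i))
    if len(set(means[in_kernel_ids])) < len(in_kernel_ids):
        log.info("assign_tissue_classes: mean-reflectance tie broken toward "
                 "lower endmember id")
    mapping = {i: "other" for i in range(em.n_em)}
    mapping[ranked[0]] = "glassy"
    mapping[ranked[-1]] = "mealy"
    mapping[ranked[len(ranked) // 2]] = "intermediate"
    return TissueAssignment(mapping, mode="auto")


def classify_pixels(ab: AbundanceMap, assign: TissueAssignment) -> np.ndarray:
    """Per-pixel tissue class by argmax over class-summed abundances.

    Multiple endmembers mapping to one class have their fractions summed.
    A pixel whose overall argmax endmember is mapped to "other" (e.g. a
    background endmember) is left unclassified and excluded from N_total.
    Exact ties between classes resolve to the class containing the lowest
    endmember id.

    Returns an int grid: -1 background, 0 unclassified, 1 glassy,
    2 intermediate, 3 mealy (see CODE_TO_CLASS).
    """
    valid = ab.valid.valid
    out = np.full(valid.shape, CODE_BACKGROUND, dtype=np.int8)
    out[valid] = CODE_UNCLASSIFIED
    frac = ab.pixel_matrix()  # (n_valid, n_em)
    if frac.size == 0:
        return out

    # overall argmax endmember decides classified vs "other"
    overall = np.argmax(frac, axis=1)  # ties -> lower em id (numpy first-match)
    other_ids = set(assign.ids_for("other"))
    dominated_by_other = np.isin(overall, list(other_ids)) if other_ids else \
        np.zeros(len(frac), dtype=bool)

    # class columns ordered so argmax's first-match rule breaks ties toward
    # the class holding the lowest endmember id
    classes = [c for c in ("glassy", "intermediate", "mealy") if assign.ids_for(c)]
    keys = [min(assign.ids_for(c)) for c in classes]
    order = np.argsort(keys, kind="stable")
    classes = [classes[i] for i in order]
    sums = np.stack([frac[:, assign.ids_for(c)].sum(axis=1) for c in classes], axis=1)
    best = np.argmax(sums, axis=1)
    codes = np.array([CLASS_CODES[c] for c in classes], dtype=np.int8)
    px_codes = codes[best]
    px_codes[dominated_by_other] = CODE_UNCLASSIFIED
    px_codes[sums.max(axis=1) <= 0] = CODE_UNCLASSIFIED
    out[valid] = px_codes
    return out


def vitreousness_index(n_glassy: int, n_intermediate: int, n_mealy: int) -> float:
    """V = (N_g + 0.5 N_i) / N_total; NaN when no pixels are classified."""
    total = n_glassy + n_intermediate + n_mealy
    if total == 0:
        return float("nan")
    return (n_glassy + 0.5 * n_intermediate) / total


def visual_index(n_glassy: int, n_intermediate: int, n_mealy: int) -> float:
    """Visual reference index: same formula at kernel (not pixel) granularity.

    Counts come from trained evaluators classifying sectioned kernels into
    glassy (>70% vitreous), intermediate (30–70%) or mealy (<30%).
    """
    return vitreousness_index(n_glassy, n_intermediate, n_mealy)


def aggregate_visual(scores) -> tuple[float, float]:
    """Cultivar-level visual vitreousness: mean and sd over evaluator x set
    scores (population sd would understate evaluator spread; sample sd used
    as for any small replicate set)."""
    arr = np.asarray(list(scores), dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def kernel_records(class_grid: np.ndarray, labels: KernelLabelMap,
                   cultivar: str = "") -> list[KernelRecord]:
    """Per-kernel class counts and V from a pixel class grid and label map."""
    records = []
    for kid in range(1, labels.n_kernels + 1):
        sel = labels.labels == kid
        codes = class_grid[sel]
        n_g = int((codes == CLASS_CODES["glassy"]).sum())
        n_i = int((codes == CLASS_CODES["intermediate"]).sum())
        n_m = int((codes == CLASS_CODES["mealy"]).sum())
        total = n_g + n_i + n_m
        records.append(KernelRecord(kid, n_g, n_i, n_m, total,
                                    vitreousness_index(n_g, n_i, n_m), cultivar))
    return records


def records_table(records: list[KernelRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "kernel_id": r.kernel_id, "cultivar": r.cultivar,
        "N_g": r.n_glassy, "N_i": r.n_intermediate, "N_m": r.n_mealy,
        "N_total": r.n_total, "V": r.v, "class": v_to_class(r.v),
    } for r in records])


def aggregate_cultivar(records: list[KernelRecord]) -> pd.DataFrame:
    """Unweighted per-cultivar mean, sd (sample) and n of kernel V values."""
    df = records_table(records)
    grouped = df.groupby("cultivar")["V"]
    out = pd.DataFrame({
        "mean_V": grouped.mean(),
        "sd_V": grouped.std(ddof=1).fillna(0.0),
        "n": grouped.size(),
    })
    return out.reset_index()


def v_to_class(v: float) -> str:
    """Kernel class from V mirroring the visual bounds: <0.3 mealy,
    [0.3, 0.7) intermediate, >=0.7 glassy (right-closed upper bin)."""
    if not np.isfinite(v):
        return "unclassified"
    if v < 0.3:
        return "mealy"
    if v < 0.7:
        return "intermediate"
    return "glassy"


def class_confusion(pred, ref) -> pd.DataFrame:
    """3x3 confusion matrix; rows = reference, columns = predicted."""
    pred = list(pred)
    ref = list(ref)
    if len(pred) != len(ref):
        raise ValueError("pred and ref must have equal length")
    for lab in (*pred, *ref):
        if lab not in ENDOSPERM_CLASSES:
            raise ValueError(f"unknown class label '{lab}'")
    mat = pd.DataFrame(0, index=list(TISSUE_CLASSES), columns=list(TISSUE_CLASSES))
    for r, p in zip(ref, pred):
        mat.loc[r, p] += 1
    mat.index.name = "reference"
    mat.columns.name = "predicted"
    return mat
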