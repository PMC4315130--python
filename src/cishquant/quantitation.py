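"""Compartment thresholding, co-localization, per-sample metrics and grading.

The measurement model follows the co-localization workflow of chromogenic
ISH quantitation: threshold the unmixed NBT/BCIP map (hybridization signal)
and the methyl green map (nuclear counterstain) inside the region of
interest, intersect them, and partition the total NBT/BCIP signal into a
nuclear part (the overlap) and a cytoplasmic part (the remainder):

    signal_cyto = total_signal_full - total_signal_overlap
    avg_signal  = total_signal / area_pixels

The per-sample mean OD is then placed on a four-tier ordinal scale
(negative / weak / moderate / strong positive) whose default cutoffs are
the published quartile boundaries 0.377, 0.5105 and 0.68025 for the
observed OD range [0.20825, 0.9455]; a data-derived quartile scale is also
supported.  The printed tier bounds leave rounding gaps (0.377 vs 0.378);
they are implemented as a total partition with upper bounds inclusive at
each cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import (
    DegeneracyError,
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
    ShapeError,
)
from .unmixing import ConcentrationMaps

__all__ = [
    "GRADE_LABELS",
    "PRINTED_CUTOFFS",
    "PRINTED_OD_MIN",
    "PRINTED_OD_MAX",
    "GradeScale",
    "CompartmentMasks",
    "SampleMetrics",
    "default_grade_scale",
    "derive_grade_scale",
    "grade_od",
    "grade_code",
    "threshold_map",
    "colocalize",
    "compute_sample_metrics",
]

GRADE_LABELS: tuple[str, ...] = ("negative", "weak_positive", "moderate", "strong_positive")

#: Published four-tier cutoffs: negative <= 0.377 < weak <= 0.5105 < moderate
#: <= 0.68025 < strong.
PRINTED_CUTOFFS: tuple[float, float, float] = (0.377, 0.5105, 0.68025)
PRINTED_OD_MIN: float = 0.20825
PRINTED_OD_MAX: float = 0.9455


@dataclass(frozen=True)
class GradeScale:
    """Four-tier ordinal OD scale defined by three ascending cutoffs."""

    cutoffs: tuple[float, float, float]
    labels: tuple[str, ...] = GRADE_LABELS
    od_min: float | None = None
    od_max: float | None = None

    def __post_init__(self) -> None:
        c1, c2, c3 = self.cutoffs
        if not (c1 < c2 < c3):
            raise DegeneracyError("grade cutoffs must be strictly increasing")
        if len(self.labels) != 4:
            raise ParameterError("a four-tier scale needs exactly four labels")
        if self.od_min is not None and self.od_max is not None:
            if not (self.od_min < c1 and c3 < self.od_max):
                raise DegeneracyError("cutoffs must lie strictly inside (od_min, od_max)")


def default_grade_scale() -> GradeScale:
    """The published quartile scale for the observed OD range."""
    return GradeScale(PRINTED_CUTOFFS, GRADE_LABELS, PRINTED_OD_MIN, PRINTED_OD_MAX)


def derive_grade_scale(od_values: Sequence[float]) -> GradeScale:
    """Quartile cutoffs (Q1, Q2, Q3) from observed per-sample mean ODs.

    Quantiles use linear interpolation between order statistics (quantile p
    at sorted position ``p * (n - 1)``).  Requires at least 4 values with a
    non-degenerate spread.
    """
    vals = np.asarray(od_values, dtype=float)
    if vals.size < 4:
        raise InsufficientDataError("deriving a quartile scale needs >= 4 OD values")
    if not np.all(np.isfinite(vals)):
        raise ParameterError("OD values must be finite")
    q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="linear")
    if not (q1 < q2 < q3):
        raise DegeneracyError("quartiles are not strictly increasing (degenerate OD distribution)")
    return GradeScale((float(q1), float(q2), float(q3)),
                      GRADE_LABELS, float(vals.min()), float(vals.max()))


def grade_od(value: float, scale: GradeScale | None = None) -> str:
    """Assign the four-tier grade of one OD value.

    Half-open binning with upper bounds inclusive: negative iff
    ``value <= c1``; weak iff ``c1 < value <= c2``; moderate iff
    ``c2 < value <= c3``; strong iff ``value > c3``.
    """
    if not math.isfinite(value) or value < 0:
        raise ParameterError(f"OD value must be finite and >= 0, got {value!r}")
    scale = scale or default_grade_scale()
    c1, c2, c3 = scale.cutoffs
    if value <= c1:
        return scale.labels[0]
    if value <= c2:
        return scale.labels[1]
    if value <= c3:
        return scale.labels[2]
    return scale.labels[3]


def grade_code(label: str, labels: Sequence[str] = GRADE_LABELS) -> int:
    """Ordinal code 1-4 of a grade label (negative=1 ... strong_positive=4)."""
    return list(labels).index(label) + 1


def threshold_map(
    conc_map: np.ndarray,
    roi: np.ndarray,
    method: str = "absolute",
    value: float | None = None,
) -> np.ndarray:
    """Binary mask of pixels whose dye amount exceeds a threshold, within ROI.

    ``method="absolute"`` uses the given OD ``value`` (strict ``>``);
    ``method="otsu"`` computes Otsu's threshold over the ROI pixels only.
    """
    conc_map = np.asarray(conc_map, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if conc_map.shape != roi.shape:
        raise ShapeError("map and ROI shapes differ")
    if not roi.any():
        raise EmptyInputError("ROI is empty")
    if method == "absolute":
        if value is None or value < 0:
            raise ParameterError("absolute thresholding requires value >= 0")
        thr = float(value)
    elif method == "otsu":
        pixels = conc_map[roi]
        if np.ptp(pixels) == 0:
            # constant region: nothing distinguishable above background
            return np.zeros_like(roi)
        thr = float(threshold_otsu(pixels))
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    return (conc_map > thr) & roi


@dataclass
class CompartmentMasks:
    """Signal / nuclear / overlap masks, all restricted to the ROI.

    ``overlap_mask`` is exactly ``nbt_mask & mg_mask`` (no morphology).
    """

    nbt_mask: np.ndarray
    mg_mask: np.ndarray
    overlap_mask: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.nbt_mask.shape
        for name in ("mg_mask", "overlap_mask", "roi_mask"):
            if getattr(self, name).shape != shape:
                raise ShapeError(f"{name} shape differs from nbt_mask")
        if np.any(self.overlap_mask != (self.nbt_mask & self.mg_mask)):
            raise ParameterError("overlap_mask must equal nbt_mask AND mg_mask")
        for name in ("nbt_mask", "mg_mask"):
            if np.any(getattr(self, name) & ~self.roi_mask):
                raise ParameterError(f"{name} extends outside roi_mask")


def colocalize(
    nbt_mask: np.ndarray,
    mg_mask: np.ndarray,
    roi_mask: np.ndarray | None = None,
) -> CompartmentMasks:
    """Intersect the NBT/BCIP and methyl green masks (exact pixelwise AND)."""
    nbt_mask = np.asarray(nbt_mask, dtype=bool)
    mg_mask = np.asarray(mg_mask, dtype=bool)
    if nbt_mask.shape != mg_mask.shape:
        raise ShapeError("mask shapes differ")
    roi = np.ones_like(nbt_mask) if roi_mask is None else np.asarray(roi_mask, dtype=bool)
    nbt = nbt_mask & roi
    mg = mg_mask & roi
    return CompartmentMasks(nbt, mg, nbt & mg, roi)


@dataclass
class SampleMetrics:
    """Per-sample quantities of the co-localization workflow.

    Degenerate compartments (zero-pixel areas) leave the affected averages
    and ratios as NaN with ``degenerate=True``; batch runs propagate them as
    missing values rather than raising mid-cohort.
    """

    area_cyto_px: int
    area_nuc_px: int
    total_signal_full: float
    total_signal_overlap: float
    signal_cyto: float
    avg_signal_cyto: float
    avg_signal_nuc: float
    nc_ratio: float
    expression_fraction_roi: float
    mean_od: float
    grade: str | None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "area_cyto_px": self.area_cyto_px,
            "area_nuc_px": self.area_nuc_px,
            "total_signal_full": self.total_signal_full,
            "total_signal_overlap": self.total_signal_overlap,
            "signal_cyto": self.signal_cyto,
            "avg_signal_cyto": self.avg_signal_cyto,
            "avg_signal_nuc": self.avg_signal_nuc,
            "nc_ratio": self.nc_ratio,
            "expression_fraction_roi": self.expression_fraction_roi,
            "mean_od": self.mean_od,
            "grade": self.grade,
            "degenerate": self.degenerate,
        }


def compute_sample_metrics(
    maps: ConcentrationMaps,
    masks: CompartmentMasks,
    scale: GradeScale | None = None,
    nbt_dye: str | None = None,
) -> SampleMetrics:
    """Partition the NBT/BCIP signal into compartments and grade the sample.

    ``total_signal_full`` sums the NBT/BCIP amount over its whole mask;
    ``total_signal_overlap`` over the nuclear overlap; the cytoplasmic
    signal is their difference (exact conservation by construction).
    Average signals divide by the respective pixel areas; ``nc_ratio`` is
    the nuclear-to-cytoplasmic ratio of those averages; ``mean_od`` (the
    graded quantity) is the mean NBT/BCIP amount over its mask.
    """
    if nbt_dye is None:
        cands = [n for n in maps.dye_names if "nbt" in n.lower() or "bcip" in n.lower()]
        nbt_dye = cands[0] if cands else maps.dye_names[0]
    nbt = maps[nbt_dye]
    if nbt.shape != masks.nbt_mask.shape:
        raise ShapeError("concentration map and masks have different shapes")
    if not masks.roi_mask.any():
        raise EmptyInputError("ROI is empty")

    n_nbt = int(masks.nbt_mask.sum())
    area_nuc = int(masks.overlap_mask.sum())
    area_cyto = n_nbt - area_nuc

    total_full = float(nbt[masks.nbt_mask].sum())
    total_overlap = float(nbt[masks.overlap_mask].sum())
    signal_cyto = total_full - total_overlap

    nan = float("nan")
    degenerate = False
    if area_cyto > 0:
        avg_cyto = signal_cyto / area_cyto
    else:
        avg_cyto, degenerate = nan, True
    if area_nuc > 0:
        avg_nuc = total_overlap / area_nuc
    else:
        avg_nuc, degenerate = nan, True
    if degenerate or avg_cyto == 0:
        nc_ratio = nan
        degenerate = True
    else:
        nc_ratio = avg_nuc / avg_cyto

    expression_fraction = n_nbt / int(masks.roi_mask.sum())
    if n_nbt > 0:
        mean_od = total_full / n_nbt
        grade = grade_od(mean_od, scale)
    else:
        mean_od, grade, degenerate = nan, None, True

    return SampleMetrics(
        area_cyto_px=area_cyto,
        area_nuc_px=area_nuc,
        total_signal_full=total_full,
        total_signal_overlap=total_overlap,
        signal_cyto=signal_cyto,
        avg_signal_cyto=avg_cyto,
        avg_signal_nuc=avg_nuc,
        nc_ratio=nc_ratio,
        expression_fraction_roi=expression_fraction,
        mean_od=mean_od,
        grade=grade,
        degenerate=degenerate,
    )
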