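"""Slide-level stromal-microenvironment metrics.

Two phenotypes are computed per slide:

* **TSR** (tumor-stroma ratio, %): ``100 * stroma_area / (tumor_area +
  stroma_area)`` — the share of the classified fibroglandular tissue that
  is connective-tissue stroma.
* **Ta-SCD** (tumor-associated stromal cellular density): nucleated cells
  per mm^2 of stroma ("standard" form), or, as a percentage, the fraction
  of the stromal area occupied by nuclei assuming a fixed mean
  single-nucleus area of 2.0e-4 mm^2.

Because the percent form is the standard form multiplied by a shared
constant, the two are exactly linearly related across slides (Pearson
r = 1 whenever both vary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Mean area of a single nucleus, mm^2, used to convert a cell count into
#: the percent of stromal area occupied by nuclei.
NUCLEUS_AREA_MM2: float = 2.0e-4


@dataclass(frozen=True)
class SMEMetrics:
    """Per-slide stromal-microenvironment phenotype summary."""

    slide_id: str
    tsr_percent: float
    tascd_standard: float  # cells per mm^2 of stroma
    tascd_percent: float
    tumor_area_mm2: float
    stroma_area_mm2: float
    tissue_area_mm2: float
    n_cells: int
    nucleus_area_mm2: float = NUCLEUS_AREA_MM2


def tsr_from_areas(stroma_area_mm2: float, tumor_area_mm2: float) -> float:
    """Tumor-stroma ratio (%) from per-class areas.

    Raises ``ValueError`` when the total classified tissue area is zero
    (such a slide fails QC and has no defined TSR).
    """
    tissue = stroma_area_mm2 + tumor_area_mm2
    if tissue <= 0:
        raise ValueError("zero tissue area: slide fails QC, TSR undefined")
    return 100.0 * stroma_area_mm2 / tissue


def compute_tsr(seg) -> float:
    """Tumor-stroma ratio (%) of a :class:`~smequant.tissue_classifier.TissueSegmentation`."""
    return tsr_from_areas(seg.stroma_area_mm2, seg.tumor_area_mm2)


def compute_tascd(
    n_cells: int,
    stroma_area_mm2: float,
    nucleus_area_mm2: float = NUCLEUS_AREA_MM2,
) -> tuple[float, float]:
    """Ta-SCD in standard (cells/mm^2) and percent form.

    percent = 100 * n_cells * nucleus_area_mm2 / stroma_area_mm2, i.e. the
    standard density times ``nucleus_area_mm2 * 100``.
    """
    if stroma_area_mm2 <= 0:
        raise ValueError("zero stroma area: Ta-SCD undefined")
    if n_cells < 0:
        raise ValueError("negative cell count")
    standard = n_cells / stroma_area_mm2
    percent = standard * nucleus_area_mm2 * 100.0
    return standard, percent


def compute_metrics(seg, detection, nucleus_area_mm2: float = NUCLEUS_AREA_MM2) -> SMEMetrics:
    """Combine a tissue segmentation and a stromal-cell detection into SMEMetrics."""
    if detection.slide_id != seg.slide_id:
        raise ValueError(
            f"segmentation is for {seg.slide_id!r} but detection is for {detection.slide_id!r}"
        )
    standard, percent = compute_tascd(detection.n_cells, seg.stroma_area_mm2, nucleus_area_mm2)
    return SMEMetrics(
        slide_id=seg.slide_id,
        tsr_percent=compute_tsr(seg),
        tascd_standard=standard,
        tascd_percent=percent,
        tumor_area_mm2=seg.tumor_area_mm2,
        stroma_area_mm2=seg.stroma_area_mm2,
        tissue_area_mm2=seg.tissue_area_mm2,
        n_cells=detection.n_cells,
        nucleus_area_mm2=nucleus_area_mm2,
    )


def percent_standard_correlation(metrics: list[SMEMetrics]) -> float:
    """Pearson r between standard and percent Ta-SCD across slides.

    With a shared nucleus-area constant the relation is exactly linear, so
    the correlation is 1.0 whenever the densities vary.  Returns ``nan``
    (degenerate) when either vector has zero variance.  Two distinct
    slides define an exact line (r = +/-1 by the sign of the slope).
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 slides for a correlation")
    standard = np.array([m.tascd_standard for m in metrics], dtype=float)
    percent = np.array([m.tascd_percent for m in metrics], dtype=float)
    if np.ptp(standard) == 0 or np.ptp(percent) == 0:
        return float("nan")
    if standard.size == 2:
        return float(np.sign((standard[1] - standard[0]) * (percent[1] - percent[0])))
    return float(stats.pearsonr(standard, percent).statistic)
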