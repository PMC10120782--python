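"""Stroma-confined nucleated-cell detection on H&E-like images.

Candidate nuclei are found by thresholding a hematoxylin-weighted optical
density (OD) channel inside the stroma mask, split by distance-transform
watershed, and then gated on size, shape (circularity), local contrast
against an annulus, and mean OD.  Contiguous dark regions too large to be
single stromal nuclei are treated as infiltrating epithelial nests and all
candidates inside them are removed, so malignant epithelium does not
inflate the stromal count.

All thresholds are exposed in :class:`DetectionParams`; the defaults were
fixed once against synthetic scenes with seeded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.morphology import dilation, disk
from skimage.segmentation import watershed

from .tissue_classifier import EXCLUDED, STROMA

# Ruifrok-Johnston H&E stain OD unit vectors (rows: hematoxylin, eosin,
# residual = normalised cross product), used for colour deconvolution of
# the detection channel.
_H = np.array([0.650, 0.704, 0.286])
_E = np.array([0.072, 0.990, 0.105])
_R = np.cross(_H, _E)
HE_STAIN_MATRIX = np.array([_H, _E, _R / np.linalg.norm(_R)])


@dataclass(frozen=True)
class DetectionParams:
    """Morphometric and photometric gates of the cell detector.

    ``nuclear_detection_weight`` blends the hematoxylin deconvolution
    channel with the mean total OD; ``nuclear_contrast_threshold`` is the
    minimum excess of candidate mean OD over a surrounding 3 um annulus.
    Dark connected regions larger than ``nest_area_threshold_um2`` are
    treated as epithelial nests and masked out.
    """

    min_nuclear_area_um2: float = 10.0
    max_nuclear_area_um2: float = 120.0
    min_circularity: float = 0.4
    nuclear_detection_weight: float = 0.8
    nuclear_contrast_threshold: float = 0.05
    min_optical_density: float = 0.30
    nest_area_threshold_um2: float = 300.0
    annulus_um: float = 3.0
    min_peak_separation_um: float = 2.0

    def validate(self) -> None:
        if not (0 < self.min_nuclear_area_um2 < self.max_nuclear_area_um2):
            raise ValueError("need 0 < min_nuclear_area < max_nuclear_area")
        if not (0 <= self.min_circularity <= 1):
            raise ValueError("min_circularity must lie in [0, 1]")


@dataclass(frozen=True)
class DetectedCell:
    row: float
    col: float
    area_um2: float
    circularity: float
    mean_od: float


@dataclass
class StromalCellDetection:
    """Stroma-confined nucleated-cell detections for one slide."""

    slide_id: str
    cells: list[DetectedCell]
    stroma_area_mm2: float
    mpp: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def optical_density_map(slide, params: DetectionParams = DetectionParams()) -> np.ndarray:
    """Detection-channel OD raster.

    Per-channel OD is ``-log10((I + 1) / 256)``; the hematoxylin
    concentration from fixed-vector deconvolution is blended with the mean
    total OD by ``nuclear_detection_weight``.  Non-negative.
    """
    od = -np.log10((slide.image.astype(np.float64) + 1.0) / 256.0)
    conc = od @ np.linalg.inv(HE_STAIN_MATRIX)
    hema = np.clip(conc[..., 0], 0.0, None)
    total = od.mean(axis=2)
    w = params.nuclear_detection_weight
    return np.clip(w * hema + (1.0 - w) * total, 0.0, None)


def _candidate_regions(det_od, dark, mpp, params):
    """Watershed-split dark components into candidate nucleus regions."""
    if not dark.any():
        return np.zeros_like(dark, dtype=np.int32), []
    dist = ndi.distance_transform_edt(dark)
    min_sep = max(1, int(round(params.min_peak_separation_um / mpp)))
    comp, _ = ndi.label(dark)
    peaks = peak_local_max(dist, min_distance=min_sep, labels=comp, exclude_border=False)
    markers = np.zeros_like(comp)
    # raster-order marker ids: deterministic tie-breaking
    for i, (r, c) in enumerate(sorted(map(tuple, peaks)), start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=dark)
    return labels, regionprops(labels, intensity_image=det_od)


def _annulus_mean(det_od, region_mask, bbox, shape, radius_px, exclude):
    """Mean OD of a ring of ``radius_px`` around one candidate region.

    Pixels in ``exclude`` (other dark objects) are left out, so the
    contrast is measured against the surrounding stroma rather than
    against touching nuclei; NaN when no stromal ring pixel exists.
    """
    r0, c0, r1, c1 = bbox
    pad = radius_px + 1
    R0, C0 = max(r0 - pad, 0), max(c0 - pad, 0)
    R1, C1 = min(r1 + pad, shape[0]), min(c1 + pad, shape[1])
    local = np.zeros((R1 - R0, C1 - C0), dtype=bool)
    local[r0 - R0 : r1 - R0, c0 - C0 : c1 - C0] = region_mask
    ring = dilation(local, disk(radius_px)) & ~local & ~exclude[R0:R1, C0:C1]
    if not ring.any():
        return np.nan
    return float(det_od[R0:R1, C0:C1][ring].mean())


def exclude_epithelial_nests(
    candidates: list[DetectedCell],
    det_od: np.ndarray,
    params: DetectionParams,
    mpp: float,
    dark: np.ndarray | None = None,
) -> list[DetectedCell]:
    """Drop candidates inside over-sized contiguous dark regions.

    Connected regions of the thresholded detection channel whose area
    exceeds ``nest_area_threshold_um2`` are taken to be infiltrating
    epithelial nests; every candidate whose centroid falls inside one is
    removed.  With an infinite threshold this is the identity.
    """
    if not np.isfinite(params.nest_area_threshold_um2):
        return list(candidates)
    if dark is None:
        dark = det_od > params.min_optical_density
    comp, n = ndi.label(dark)
    if n == 0:
        return list(candidates)
    areas_px = np.bincount(comp.ravel())
    nest_ids = np.flatnonzero(areas_px * mpp**2 > params.nest_area_threshold_um2)
    nest_ids = nest_ids[nest_ids > 0]
    if nest_ids.size == 0:
        return list(candidates)
    nest_mask = np.isin(comp, nest_ids)
    kept = []
    for cell in candidates:
        r, c = int(round(cell.row)), int(round(cell.col))
        r = min(max(r, 0), dark.shape[0] - 1)
        c = min(max(c, 0), dark.shape[1] - 1)
        if not nest_mask[r, c]:
            kept.append(cell)
    return kept


def detect_stromal_cells(
    slide, seg, params: DetectionParams = DetectionParams()
) -> StromalCellDetection:
    """Detect nucleated cells confined to the stroma of one slide.

    Deterministic: identical inputs give identical detections.  Raises
    ``ValueError`` when the segmentation contains no stroma (slide should
    go back to QC).
    """
    params.validate()
    if seg.slide_id != slide.slide_id:
        raise ValueError("segmentation and slide refer to different slides")
    if seg.stroma_area_mm2 <= 0:
        raise ValueError("segmentation has zero stroma area; check slide QC")
    mpp = slide.mpp
    stroma = seg.label_raster == STROMA
    if slide.excluded_mask is not None:
        stroma &= ~slide.excluded_mask
    stroma &= seg.label_raster != EXCLUDED

    det_od = optical_density_map(slide, params)
    dark = (det_od > params.min_optical_density) & stroma

    labels, regions = _candidate_regions(det_od, dark, mpp, params)
    annulus_px = max(1, int(round(params.annulus_um / mpp)))
    px_area = mpp**2

    candidates: list[DetectedCell] = []
    for reg in regions:
        area_um2 = reg.area * px_area
        if not (params.min_nuclear_area_um2 <= area_um2 <= params.max_nuclear_area_um2):
            continue
        perim = reg.perimeter
        circ = 1.0 if perim == 0 else min(4.0 * np.pi * reg.area / perim**2, 1.0)
        if circ < params.min_circularity:
            continue
        mean_od = float(reg.intensity_mean)
        if mean_od < params.min_optical_density:
            continue
        ann = _annulus_mean(det_od, reg.image, reg.bbox, det_od.shape, annulus_px, dark)
        if np.isfinite(ann) and (mean_od - ann) < params.nuclear_contrast_threshold:
            continue
        r, c = reg.centroid
        ri, ci = int(round(r)), int(round(c))
        ri = min(max(ri, 0), stroma.shape[0] - 1)
        ci = min(max(ci, 0), stroma.shape[1] - 1)
        if not stroma[ri, ci]:
            continue
        candidates.append(DetectedCell(row=r, col=c, area_um2=area_um2, circularity=circ, mean_od=mean_od))

    cells = exclude_epithelial_nests(candidates, det_od, params, mpp, dark=dark)
    return StromalCellDetection(
        slide_id=slide.slide_id, cells=cells, stroma_area_mm2=seg.stroma_area_mm2, mpp=mpp
    )


def count_in_region(
    detection: StromalCellDetection,
    row0_um: float,
    col0_um: float,
    side_um: float = 500.0,
) -> int:
    """Number of detected centroids in a half-open square counting frame.

    The frame is ``[row0_um, row0_um + side_um) x [col0_um, col0_um +
    side_um)`` in micron coordinates (pixel * mpp).  Raises ``ValueError``
    when the frame extends outside the slide.
    """
    mpp = detection.mpp
    if row0_um < 0 or col0_um < 0:
        raise ValueError("counting frame extends outside the image")
    n = 0
    for cell in detection.cells:
        r_um, c_um = cell.row * mpp, cell.col * mpp
        if row0_um <= r_um < row0_um + side_um and col0_um <= c_um < col0_um + side_um:
            n += 1
    return n


def count_in_region_px(
    detection: StromalCellDetection, shape_px: tuple[int, int], row0_um: float, col0_um: float, side_um: float = 500.0
) -> int:
    """As :func:`count_in_region` but with explicit slide shape for bounds checks."""
    h_um, w_um = shape_px[0] * detection.mpp, shape_px[1] * detection.mpp
    if row0_um < 0 or col0_um < 0 or row0_um + side_um > h_um or col0_um + side_um > w_um:
        raise ValueError("counting frame extends outside the image")
    return count_in_region(detection, row0_um, col0_um, side_um)


def concordance_vs_reference(auto_counts, reference_counts) -> float:
    """Pearson correlation between automated and reference region counts.

    Mirrors a validation against manual pathologist counts; here the
    reference is typically the seeded ground truth.  Returns ``nan`` when
    either vector has zero variance.
    """
    x = np.asarray(auto_counts, dtype=float)
    y = np.asarray(reference_counts, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
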