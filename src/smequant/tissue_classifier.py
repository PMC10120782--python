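"""Random-forest tumor/stroma segmentation from sparse point annotations.

A slide is segmented in three steps: (1) non-tissue background is removed
by a luminance threshold, (2) the remaining pixels are classified
tumor/stroma by a random forest over local colour/texture window features
on a regular grid, and (3) grid predictions are upsampled to full
resolution by nearest neighbour so that area accounting stays exact.
Per-class areas are reported in mm^2 via ``pixels * mpp^2 / 1e6``.

Features per window (length :data:`FEATURE_LENGTH`): mean and SD of the
three RGB channels and of the hematoxylin and eosin optical-density
channels (Ruifrok-Johnston deconvolution), mean and SD of the Sobel
gradient magnitude, and the Shannon entropy of an 8-bin grey-level
histogram.  All window statistics use reflective padding at image borders
and are pure functions of the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.color import rgb2gray, rgb2hed
from skimage.filters import sobel
from sklearn.ensemble import RandomForestClassifier

BACKGROUND = 0
TUMOR = 1
STROMA = 2
EXCLUDED = 3

CLASS_NAMES = {"tumor": TUMOR, "stroma": STROMA}

N_ENTROPY_BINS = 8
#: length of the feature vector: (3 RGB + 2 stain) * (mean, sd) + gradient
#: (mean, sd) + grey-histogram entropy
FEATURE_LENGTH = 13


@dataclass(frozen=True)
class TissueClassifierConfig:
    window_um: float = 32.0  # window side, microns (32 px at mpp 1.0)
    stride_px: int = 4
    n_estimators: int = 100
    background_luminance: float = 0.9  # fraction of max grey level
    seed: int = 0

    def window_px(self, mpp: float) -> int:
        return max(8, int(round(self.window_um / mpp)))


@dataclass
class AnnotationSet:
    """Sparse labelled training points: (slide_id, row, col, class)."""

    points: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        for p in self.points:
            if p[3] not in CLASS_NAMES:
                raise ValueError(f"unknown class {p[3]!r}; expected tumor or stroma")

    def __len__(self) -> int:
        return len(self.points)

    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in CLASS_NAMES}
        for p in self.points:
            counts[p[3]] += 1
        return counts


@dataclass
class TissueSegmentation:
    """Per-pixel tissue labels and per-class areas for one slide."""

    slide_id: str
    label_raster: np.ndarray  # uint8 in {BACKGROUND, TUMOR, STROMA, EXCLUDED}
    tumor_area_mm2: float
    stroma_area_mm2: float
    tissue_area_mm2: float
    mpp: float


@dataclass
class TissueModel:
    forest: RandomForestClassifier
    config: TissueClassifierConfig
    oob_accuracy: float
    classes: tuple[str, ...] = ("tumor", "stroma")


class FeatureExtractor:
    """Window-statistic features over one slide via integral images.

    Precomputes per-pixel transform maps (RGB, H/E optical density, Sobel
    gradient magnitude, 8-level grey quantisation) once per slide; window
    means/SDs and histogram entropies are then O(1) per query point.
    """

    def __init__(self, slide, window_px: int | None = None):
        cfg_window = window_px if window_px is not None else 32
        self.window = int(cfg_window)
        img = slide.image.astype(np.float64) / 255.0
        hed = rgb2hed(slide.image)
        gray = rgb2gray(slide.image)
        grad = sobel(gray)
        channels = [img[..., 0], img[..., 1], img[..., 2], hed[..., 0], hed[..., 1], grad]
        bins = np.clip((gray * N_ENTROPY_BINS).astype(int), 0, N_ENTROPY_BINS - 1)

        w = self.window
        lo, hi = w // 2, w - w // 2
        def integral(m):
            p = np.pad(m, ((lo, hi), (lo, hi)), mode="reflect")
            s = np.zeros((p.shape[0] + 1, p.shape[1] + 1))
            np.cumsum(np.cumsum(p, axis=0), axis=1, out=s[1:, 1:])
            return s

        self._sums = [integral(c) for c in channels]
        self._sqsums = [integral(c * c) for c in channels]
        self._bin_sums = [integral((bins == b).astype(np.float64)) for b in range(N_ENTROPY_BINS)]
        self.shape = gray.shape

    def _box(self, S, rows, cols):
        w = self.window
        return S[rows + w, cols + w] - S[rows, cols + w] - S[rows + w, cols] + S[rows, cols]

    def features(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=np.intp)
        cols = np.asarray(cols, dtype=np.intp)
        n_px = float(self.window**2)
        out = np.empty((rows.size, FEATURE_LENGTH))
        j = 0
        for S, Q in zip(self._sums, self._sqsums):
            s = self._box(S, rows, cols)
            q = self._box(Q, rows, cols)
            mean = s / n_px
            var = np.maximum(q / n_px - mean**2, 0.0)
            out[:, j] = mean
            out[:, j + 1] = np.sqrt(var)
            j += 2
        probs = np.stack([self._box(S, rows, cols) / n_px for S in self._bin_sums], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(probs > 0, np.log(probs), 0.0)
        out[:, j] = -(probs * logp).sum(axis=1)
        return out


def extract_features(slide, row: int, col: int, window_px: int = 32) -> np.ndarray:
    """Feature vector of one window (convenience wrapper; see FeatureExtractor)."""
    fx = FeatureExtractor(slide, window_px)
    return fx.features(np.array([row]), np.array([col]))[0]


def train_tissue_classifier(
    slides,
    annotations: AnnotationSet,
    config: TissueClassifierConfig = TissueClassifierConfig(),
) -> TissueModel:
    """Fit a random forest on window features at the annotation points.

    ``slides`` maps slide_id -> Slide (a bare Slide is accepted when all
    points reference it).  Requires at least two points per class; reports
    out-of-bag accuracy.
    """
    if not isinstance(slides, dict):
        slides = {sid: slides for sid in {p[0] for p in annotations.points}}
    counts = annotations.class_counts()
    for name, n in counts.items():
        if n < 2:
            raise ValueError(
                f"need at least 2 annotation points per class; got {n} for {name!r}"
            )

    X, y = [], []
    for sid in sorted({p[0] for p in annotations.points}):
        slide = slides[sid]
        fx = FeatureExtractor(slide, config.window_px(slide.mpp))
        pts = [(r, c, cls) for s, r, c, cls in annotations.points if s == sid]
        rows = np.array([p[0] for p in pts])
        cols = np.array([p[1] for p in pts])
        X.append(fx.features(rows, cols))
        y += [p[2] for p in pts]
    X = np.vstack(X)
    y = np.array(y)

    forest = RandomForestClassifier(
        n_estimators=config.n_estimators,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TissueModel(forest=forest, config=config, oob_accuracy=float(forest.oob_score_))


def segment_slide(model: TissueModel, slide, stride_px: int | None = None) -> TissueSegmentation:
    """Segment one slide into background / tumor / stroma / excluded.

    Background is assigned first by the luminance threshold; remaining
    pixels are classified on a grid of ``stride_px`` and upsampled by
    nearest neighbour; the slide's ``excluded_mask`` is applied last.
    """
    if slide.mpp is None:
        raise ValueError("slide has no mpp; areas in mm^2 would be meaningless")
    cfg = model.config
    stride = stride_px if stride_px is not None else cfg.stride_px
    h, w = slide.shape

    gray = rgb2gray(slide.image)
    background = gray >= cfg.background_luminance

    fx = FeatureExtractor(slide, cfg.window_px(slide.mpp))
    grid_r = np.arange(0, h, stride)
    grid_c = np.arange(0, w, stride)
    rr, cc = np.meshgrid(grid_r, grid_c, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    grid_labels = np.full(rr.size, BACKGROUND, dtype=np.uint8)
    fg = ~background[rr, cc]
    if fg.any():
        pred = model.forest.predict(fx.features(rr[fg], cc[fg]))
        grid_labels[fg] = np.where(pred == "tumor", TUMOR, STROMA)
    grid_labels = grid_labels.reshape(grid_r.size, grid_c.size)

    label = np.repeat(np.repeat(grid_labels, stride, axis=0), stride, axis=1)[:h, :w]
    label[background] = BACKGROUND
    if slide.excluded_mask is not None:
        label[slide.excluded_mask] = EXCLUDED

    factor = slide.mpp**2 / 1e6
    tumor_area = int((label == TUMOR).sum()) * factor
    stroma_area = int((label == STROMA).sum()) * factor
    return TissueSegmentation(
        slide_id=slide.slide_id,
        label_raster=label,
        tumor_area_mm2=tumor_area,
        stroma_area_mm2=stroma_area,
        tissue_area_mm2=tumor_area + stroma_area,
        mpp=slide.mpp,
    )


@dataclass
class ConcordanceReport:
    rho_tumor: float
    rho_stroma: float
    n_slides: int
    note: str = ""


def reproducibility_check(model_a, model_b, slides, stride_px: int | None = None) -> ConcordanceReport:
    """Spearman concordance of per-slide areas between two trained models.

    Mirrors a two-annotator design: each model is applied to the same
    slides and the per-slide tumor and stroma area vectors are compared.
    """
    slides = list(slides)
    if len(slides) < 3:
        raise ValueError("need at least 3 slides for a rank correlation")
    areas = {m: {"tumor": [], "stroma": []} for m in ("a", "b")}
    for slide in slides:
        for key, model in (("a", model_a), ("b", model_b)):
            seg = segment_slide(model, slide, stride_px)
            areas[key]["tumor"].append(seg.tumor_area_mm2)
            areas[key]["stroma"].append(seg.stroma_area_mm2)
    note = ""
    rhos = {}
    for cls in ("tumor", "stroma"):
        x = np.array(areas["a"][cls])
        y = np.array(areas["b"][cls])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rhos[cls] = float("nan")
            note = f"degenerate {cls} area variance; rho undefined"
        else:
            rhos[cls] = float(stats.spearmanr(x, y).statistic)
    return ConcordanceReport(
        rho_tumor=rhos["tumor"], rho_stroma=rhos["stroma"], n_slides=len(slides), note=note
    )
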