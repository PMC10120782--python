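"""File-format helpers: TIFF/PNG rasters, CSV tables, YAML parameter files.

Slides are 8-bit RGB TIFF or PNG; label rasters are single-channel TIFF
(0 = background, 1 = tumor, 2 = stroma, 3 = excluded); point tables
(annotations, nuclei, detections) are plain CSV; scene/detection/effect
parameters round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cell_detect import DetectionParams, StromalCellDetection
from .synthslide import SceneParams, Slide
from .tissue_classifier import AnnotationSet


def write_slide(path, slide: Slide) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, slide.image)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray(slide.image).save(path)
    else:
        raise ValueError(f"unsupported slide format {path.suffix!r} (use .tif/.tiff/.png)")


def read_slide(path, slide_id: str | None = None, mpp: float = 1.0) -> Slide:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        image = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image

        image = np.asarray(Image.open(path).convert("RGB"))
    else:
        raise ValueError(f"unsupported slide format {path.suffix!r}")
    return Slide(slide_id=slide_id or path.stem, image=image, mpp=mpp)


def write_label_raster(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.uint8))


def read_label_raster(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_annotations(path, annotations: AnnotationSet) -> None:
    pd.DataFrame(annotations.points, columns=["slide_id", "row", "col", "class"]).to_csv(
        path, index=False
    )


def read_annotations(path) -> AnnotationSet:
    df = pd.read_csv(path)
    return AnnotationSet(
        points=[
            (str(s), int(r), int(c), str(k))
            for s, r, c, k in zip(df["slide_id"], df["row"], df["col"], df["class"])
        ]
    )


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, keeping the literal 'n/a' category distinct from
    genuinely missing (empty) cells and categorical codes (e.g. grade) as
    strings."""
    from .synthcohort import CATEGORY_ORDERS

    return pd.read_csv(
        path,
        keep_default_na=False,
        na_values=[""],
        dtype={c: str for c in CATEGORY_ORDERS},
    )


def annotations_to_geojson(annotations: AnnotationSet) -> dict:
    """Minimal GeoJSON point dialect: (x, y) = (col, row), class in properties."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [int(c), int(r)]},
                "properties": {"slide_id": sid, "class": cls},
            }
            for sid, r, c, cls in annotations.points
        ],
    }


def geojson_to_annotations(obj: dict) -> AnnotationSet:
    points = []
    for feat in obj.get("features", []):
        c, r = feat["geometry"]["coordinates"]
        props = feat["properties"]
        points.append((str(props["slide_id"]), int(r), int(c), str(props["class"])))
    return AnnotationSet(points=points)


def write_detections(path, detection: StromalCellDetection) -> None:
    pd.DataFrame(
        [
            {
                "slide_id": detection.slide_id,
                "row": c.row,
                "col": c.col,
                "area_um2": c.area_um2,
                "circularity": c.circularity,
                "mean_od": c.mean_od,
            }
            for c in detection.cells
        ],
        columns=["slide_id", "row", "col", "area_um2", "circularity", "mean_od"],
    ).to_csv(path, index=False)


def write_area_table(path, segmentations) -> None:
    pd.DataFrame(
        [
            {
                "slide_id": s.slide_id,
                "tumor_area_mm2": s.tumor_area_mm2,
                "stroma_area_mm2": s.stroma_area_mm2,
                "tissue_area_mm2": s.tissue_area_mm2,
            }
            for s in segmentations
        ]
    ).to_csv(path, index=False)


def write_metrics_table(path, metrics) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in metrics]).to_csv(path, index=False)


def write_params_yaml(path, params) -> None:
    data = dataclasses.asdict(params)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_scene_params(path) -> SceneParams:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("nest_radius_um", "nucleus_radius_um"):
        if key in data:
            data[key] = tuple(data[key])
    return SceneParams(**data)


def read_detection_params(path) -> DetectionParams:
    return DetectionParams(**yaml.safe_load(Path(path).read_text()))
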