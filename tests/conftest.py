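"""Shared fixtures: small synthetic scenes and a trained tissue model."""

import numpy as np
import pytest

from smequant import synthslide as ss
from smequant import tissue_classifier as tc


@pytest.fixture(scope="session")
def small_params():
    """A compact scene used by most unit tests (fast to render/segment)."""
    return ss.SceneParams(seed=11, height_px=288, width_px=288, n_tumor_nests=3)


@pytest.fixture(scope="session")
def small_scene(small_params):
    return ss.generate_slide(small_params, slide_id="unit")


@pytest.fixture(scope="session")
def small_model(small_scene):
    slide, gt = small_scene
    ann = ss.sample_annotation_points(gt, seed=12, slide_id="unit")
    return tc.train_tissue_classifier(slide, ann)


@pytest.fixture(scope="session")
def small_segmentation(small_model, small_scene):
    slide, _ = small_scene
    return tc.segment_slide(small_model, slide)


def dice_coefficient(label_raster, truth_mask, value):
    pred = label_raster == value
    true = truth_mask == value
    denom = pred.sum() + true.sum()
    return 2.0 * (pred & true).sum() / denom if denom else np.nan
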