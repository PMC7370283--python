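import warnings

import numpy as np
import pytest

from sproutassay.imaging import max_project
from sproutassay.segmentation import SegmentationParams, segment_chip
from sproutassay.synthetic import SproutingModelParams, render_chip_stack


@pytest.fixture(scope="session")
def default_params():
    return SproutingModelParams(seed=7)


@pytest.fixture(scope="session")
def rendered_chip(default_params):
    """One default noisy control render with its ground truth (shared; ~1 s)."""
    return render_chip_stack(default_params, seed=7)


@pytest.fixture(scope="session")
def noisefree_chip(default_params):
    """Noise-free control render (geometry jitter only)."""
    return render_chip_stack(default_params, seed=7, noise=False)


@pytest.fixture(scope="session")
def segmented_chip(rendered_chip, default_params):
    stack, truth = rendered_chip
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = segment_chip(
            max_project(stack),
            SegmentationParams(baseline_y=default_params.baseline_y),
        )
    return seg, truth


def match_points(detected: np.ndarray, truth: np.ndarray, tol_um: float = 5.0):
    """(recall, precision) of detected vs ground-truth 2D points."""
    from scipy.spatial import cKDTree

    if len(truth) == 0 or len(detected) == 0:
        return 0.0, 0.0
    d_truth, _ = cKDTree(detected).query(truth)
    d_det, _ = cKDTree(truth).query(detected)
    return float(np.mean(d_truth <= tol_um)), float(np.mean(d_det <= tol_um))
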