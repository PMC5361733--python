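import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fociscope as fs

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_render() -> fs.RenderParams:
    """Small noise-free field holding a handful of nuclei."""
    return fs.RenderParams(shape_zyx=(14, 330, 330), noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_render() -> fs.RenderParams:
    return fs.RenderParams(shape_zyx=(14, 330, 330), noise_sd=5.0)


@pytest.fixture(scope="session")
def reference_table():
    return fs.load_reference_summary()


def match_records_to_truth(nuclei: fs.LabeledNuclei, truth: fs.GroundTruth):
    """Map each segmented nucleus (1..n) to the simulator nucleus whose true
    ellipsoid contains its centroid; 0 if none."""
    true_labels = fs.rasterize_truth(truth)
    ids = []
    for c in np.rint(nuclei.centroids).astype(int):
        ids.append(int(true_labels[tuple(np.clip(c, 0, np.array(true_labels.shape) - 1))]))
    return ids
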