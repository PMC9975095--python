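import numpy as np
import pytest

from gliamorph import synthgen, pipeline
from gliamorph.datatypes import CalibratedImage


@pytest.fixture(scope="session")
def small_scene():
    """A 20-cell noise-free mixed scene with ground truth (session-cached)."""
    channels, truth = synthgen.generate_scene(
        {"ramified": 8, "intermediate": 6, "amoeboid": 6},
        seed=1,
        blur_sigma_um=0.0,
        noise_sigma=0.0,
    )
    return channels, truth


@pytest.fixture(scope="session")
def small_result(small_scene):
    channels, truth = small_scene
    cfg = pipeline.PipelineConfig(pixel_size_um=channels.pixel_size_um)
    return pipeline.analyze_channels(channels, cfg), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, shape=(40, 40), sigma=2.0, q=0.7, min_px=5):
    """A random single-component mask of at least ``min_px`` pixels.

    Components are taken 4-connected so that the pixel boundary and the
    marching-squares contour describe the same object (diagonal-only necks
    are ambiguous between the two conventions).
    """
    from scipy import ndimage as ndi

    for _ in range(50):
        noise = ndi.gaussian_filter(rng.normal(size=shape), sigma)
        mask = noise > np.quantile(noise, q)
        labels, n = ndi.label(mask)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        big = int(np.argmax(sizes))
        comp = labels == big
        if comp.sum() >= min_px:
            return comp
    raise RuntimeError("could not draw a blob")


def match_truth(result, truth):
    """Pair each detected component/record with its ground-truth cell."""
    pairs = []
    for comp, rec in zip(result.components, result.records):
        nr, nc = comp.nucleus_points[0]
        cell = min(
            truth.cells,
            key=lambda t: (t["nucleus_center_px"][0] - nr) ** 2
            + (t["nucleus_center_px"][1] - nc) ** 2,
        )
        pairs.append((cell, comp, rec))
    return pairs


@pytest.fixture
def calibrated(rng):
    def make(pixels, pixel_size_um=1.0, **kw):
        return CalibratedImage(np.asarray(pixels, float), pixel_size_um, **kw)

    return make
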