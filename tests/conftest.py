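import warnings

import numpy as np
import pytest

from veinseg import RunConfig, generate

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def low_noise_sample():
    """One 256x256 synthetic sample at low noise, shared across tests."""
    return generate(seed=3, noise_sigma=2.0)


@pytest.fixture(scope="session")
def branched_sample():
    """Sample with a junction planted inside the distal collection box."""
    return generate(seed=1000, noise_sigma=2.0, n_branches=1,
                    junction_region=(20, 80, 48, 208))


@pytest.fixture(scope="session")
def fused_features(low_noise_sample, default_config):
    """Fused 5-scale feature image of the shared low-noise sample."""
    from veinseg import compute_block_grid, filter_image, fuse_orientations
    from veinseg.gabor import extract_roi_and_pad

    padded, _ = extract_roi_and_pad(low_noise_sample.image,
                                    default_config.gabor.target_size)
    grid = compute_block_grid(padded, default_config.gabor)
    stack = filter_image(padded, grid, default_config.gabor)
    return fuse_orientations(stack).astype(float)


def random_seg_graph(rng, h, w, neighborhood=4):
    """Random capacitated pixel graph for min-cut oracle tests."""
    from veinseg.segmentation import SegGraph

    idx = np.arange(h * w).reshape(h, w)
    shifts = [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if neighborhood == 8 else [])
    pa, pb = [], []
    for dr, dc in shifts:
        src = idx[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
        dst = idx[max(0, dr):h + min(0, dr), max(0, dc):w + min(0, dc)]
        pa += list(src.ravel())
        pb += list(dst.ravel())
    return SegGraph(
        shape=(h, w),
        source_caps=rng.uniform(0, 5, (h, w)),
        sink_caps=rng.uniform(0, 5, (h, w)),
        pair_a=np.asarray(pa, dtype=int),
        pair_b=np.asarray(pb, dtype=int),
        pair_caps=rng.uniform(0, 3, len(pa)),
    )


def brute_force_min_energy(graph):
    """Exhaustive search over all 2^n labelings (independent oracle)."""
    import itertools

    h, w = graph.shape
    n = h * w
    best = np.inf
    for bits in itertools.product((0, 1), repeat=n):
        e = graph.energy(np.asarray(bits).reshape(h, w))
        best = min(best, e)
    return best
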