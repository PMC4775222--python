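import numpy as np
import pytest

from edgepulse import segmentation, synthetic


@pytest.fixture(scope="session")
def noiseless_tissue():
    """Small noiseless oscillating patch shared by rendering/tracking tests."""
    cfg = synthetic.SyntheticTissueConfig(n_frames=14, dt=10.0, noise_sd=0.0, seed=11)
    return synthetic.generate_oscillating_tissue(cfg)


@pytest.fixture(scope="session")
def noiseless_movie(noiseless_tissue):
    tissue, _truth = noiseless_tissue
    stack, labels = synthetic.generate_membrane_movie(
        tissue, psf_sigma=0.2, snr=np.inf, seed=1
    )
    return stack, labels


@pytest.fixture(scope="session")
def first_frame_seeds(noiseless_tissue, noiseless_movie):
    """Centroid seeds for frame 0 plus a background seed in a dark corner."""
    tissue, _ = noiseless_tissue
    stack, _ = noiseless_movie
    seeds = [(0, 2.0, 2.0)]
    for cid in tissue.cell_ids:
        c = tissue.polygons[cid][0].mean(axis=0) / stack.pixel_size
        seeds.append((cid, float(c[0]), float(c[1])))
    return segmentation.SeedSet(frame=0, seeds=seeds)
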