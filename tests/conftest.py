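import numpy as np
import pandas as pd
import pytest

from stormclust.loc_io import LocalizationTable


def make_table(
    coords,
    photon_count=None,
    sigma_x=None,
    image_id="test-img",
    channel="default",
):
    """Build a LocalizationTable from bare coordinates for tests."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    if photon_count is None:
        photon_count = np.full(n, 2000.0)
    if sigma_x is None:
        sigma_x = np.full(n, 15.0)
    data = pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "photon_count": np.asarray(photon_count, dtype=float),
            "sigma_x": np.asarray(sigma_x, dtype=float),
            "channel": channel,
        }
    )
    return LocalizationTable(data=data, image_id=image_id)


def random_scene(rng, n_blobs=3, blob_size=30, blob_sigma=40.0, n_noise=50,
                 extent=2000.0, pc_split=True):
    """Random mixture of Gaussian blobs and uniform background.

    Blob members optionally get distinct (bimodal) photon counts so that
    voxel-mean photon-count gates have something to act on.
    """
    parts, pcs = [], []
    for _ in range(n_blobs):
        center = rng.uniform(200, extent - 200, size=3)
        pts = rng.normal(center, blob_sigma, size=(blob_size, 3))
        parts.append(pts)
        level = rng.choice([800.0, 3000.0, 8000.0]) if pc_split else 2000.0
        pcs.append(rng.lognormal(np.log(level), 0.4, size=blob_size))
    parts.append(rng.uniform(0, extent, size=(n_noise, 3)))
    pcs.append(rng.lognormal(np.log(1500.0), 0.5, size=n_noise))
    coords = np.vstack(parts)
    pc = np.concatenate(pcs)
    return make_table(coords, photon_count=pc)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
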