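import numpy as np
import pandas as pd
import pytest

from birdscape import raster, syngen


@pytest.fixture(scope="session")
def small_landscape():
    """A 2 km synthetic city used by several suites (cheap to generate)."""
    cfg = syngen.LandscapeConfig(
        grid_size_m=2000.0, centre_xy=(1000.0, 1000.0), seed=7
    )
    ndvi, ndsm, mask = syngen.generate_landscape(cfg)
    return cfg, ndvi, ndsm, mask


@pytest.fixture(scope="session")
def small_sites(small_landscape):
    cfg, _, _, _ = small_landscape
    return syngen.make_sites(
        20, cfg.grid_size_m, margin_m=450.0, min_separation_m=150.0, seed=11
    )


@pytest.fixture(scope="session")
def small_detections(small_landscape, small_sites):
    cfg, ndvi, _, _ = small_landscape
    pool = syngen.generate_species_pool(15, seed=5)
    ndvi_at = [
        raster.buffer_mean(ndvi, (r.x, r.y), 100.0) for r in small_sites.itertuples()
    ]
    dets = syngen.simulate_detections(
        small_sites,
        ndvi_at,
        pool,
        days=7.0,
        seed=13,
        noise_fraction=0.1,
        n_injected_singletons=3,
    )
    return pool, np.asarray(ndvi_at), dets


def constant_raster(value, n=20, res=10.0, origin=(0.0, 200.0)):
    return raster.RasterLayer(origin, res, np.full((n, n), float(value)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
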