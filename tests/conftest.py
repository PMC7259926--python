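import numpy as np
import pytest

import ecoprov as ep


@pytest.fixture(scope="session")
def small_field():
    """24x48 blob field, 3 planted provinces, moderate noise."""
    spec = ep.SyntheticSpec(n_lat=24, n_lon=48, n_provinces=3, noise_sd=0.2, seed=1)
    return ep.generate_field(spec)


@pytest.fixture(scope="session")
def small_features(small_field):
    return ep.transform_features(ep.apply_masks(small_field))


@pytest.fixture(scope="session")
def small_embedding(small_features):
    return ep.embed(small_features, perplexity=40, n_iter=300, seed=2)


@pytest.fixture(scope="session")
def small_labeling(small_field, small_features, small_embedding):
    scan = ep.scan_eps(small_embedding, ep.auto_eps_grid(small_embedding),
                       [ep.scaled_min_pts(small_features.n)])
    params = ep.select_eps(scan)
    lab = ep.dbscan(small_embedding, params)
    lab.cell_ids = small_features.cell_ids
    return lab


@pytest.fixture(scope="session")
def tiny_labeled_field():
    """Zero-noise 12x24 field with 3 provinces and its perfect labeling."""
    spec = ep.SyntheticSpec(n_lat=12, n_lon=24, n_provinces=3, geometry="zonal_bands",
                            noise_sd=0.0, low_biomass_frac=0.0, seed=9)
    field = ep.generate_field(spec)
    fm = ep.apply_masks(field)
    truth = field.true_labels.reshape(-1)[fm.cell_ids]
    lab = ep.ProvinceLabeling(labels=truth, params=ep.DBSCANParams(eps=1.0, min_pts=1),
                              cell_ids=fm.cell_ids)
    return field, lab


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
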