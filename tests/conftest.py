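"""Shared fixtures: synthetic datasets and (expensive) fitted models.

Training fixtures are session-scoped so the integration models are fitted
once and inspected by several tests.
"""

import numpy as np
import pandas as pd
import pytest

import scfuse as sf


@pytest.fixture(scope="session")
def easy_batches():
    """Two-batch synthetic at study-condition defaults (seed 0), with truth."""
    ds_list, truth = sf.simulate_batches(seed=0)
    return ds_list, truth


@pytest.fixture(scope="session")
def easy_lognorm(easy_batches):
    ds_list, truth = easy_batches
    return [sf.normalize_log(d) for d in ds_list], truth


@pytest.fixture(scope="session")
def vipcca_result(easy_lognorm):
    ds_list, _ = easy_lognorm
    return sf.fit_vipcca(ds_list, sf.TrainingConfig(seed=0))


@pytest.fixture(scope="session")
def davae_result(easy_lognorm):
    ds_list, _ = easy_lognorm
    return sf.fit_davae(ds_list, sf.TrainingConfig(seed=0))


@pytest.fixture(scope="session")
def vimcca_inputs():
    ds_x, ds_y, truth = sf.simulate_paired(seed=0)
    return sf.normalize_log(ds_x), sf.normalize_log(ds_y), truth


@pytest.fixture(scope="session")
def vimcca_result(vimcca_inputs):
    ds_x, ds_y, _ = vimcca_inputs
    return sf.fit_vimcca(ds_x, ds_y, sf.TrainingConfig(seed=0))


@pytest.fixture(scope="session")
def spatial_sim():
    return sf.simulate_spatial(seed=0)


@pytest.fixture(scope="session")
def grid_coords():
    side = np.arange(10.0)
    xx, yy = np.meshgrid(side, side, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


@pytest.fixture()
def tiny_dataset():
    """3 cells x 2 features with coordinates, for container/IO tests."""
    return sf.OmicsDataset(
        counts=np.array([[1.0, 2.0], [0.0, 5.0], [3.0, 0.0]]),
        obs_names=pd.Index(["c1", "c2", "c3"]),
        var_names=pd.Index(["gA", "gB"]),
        batch=np.array(["0", "0", "1"]),
        coords=np.array([[0.0, 0.5], [1.0, 1.5], [2.0, 0.25]]),
    )
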