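import warnings

import numpy as np
import pytest

import pathstrings as ps


@pytest.fixture
def route_spec():
    return ps.default_route_spec(seed=0)


@pytest.fixture
def ensemble(route_spec):
    return ps.generate_pathway_ensemble(route_spec, 80)


@pytest.fixture
def pathways(ensemble, route_spec):
    flat = np.concatenate(ensemble.trajectories)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ps.extract_cmd(flat, route_spec.source_id, route_spec.target_id)


@pytest.fixture
def blob_data():
    from pathstrings.synthetic import default_blob_centroids

    return ps.generate_blobs(default_blob_centroids(), sigma=8.0, n_per=200, seed=0)
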