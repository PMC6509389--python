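import numpy as np
import pytest

from samplescape import (
    GenotypeTable,
    SyntheticConfig,
    generate_dataset,
)
from samplescape.mlpe import CandidateModel
from samplescape.resistance import (
    SurfaceSpec,
    parameterize,
    resistance_distances,
    uniform_ibd_predictor,
)


@pytest.fixture
def tiny_table():
    """4 individuals at 2 sites, 2 loci, one missing call."""
    calls = np.array(
        [
            [[1, 1], [2, 3]],
            [[1, 2], [2, 2]],
            [[1, 1], [0, 0]],
            [[2, 2], [3, 3]],
        ]
    )
    return GenotypeTable(
        ["a1", "a2", "b1", "b2"],
        np.array(["A", "A", "B", "B"], object),
        ["L1", "L2"],
        calls,
    )


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study: 12 sites on a 30x30 landscape, ~60 individuals."""
    sizes = (11, 11, 12, 13, 14, 15, 1, 2, 2, 3, 3, 4)
    return SyntheticConfig(
        nrows=30, ncols=30, autocorr_sigma=3.0, n_sites=12,
        min_separation=3.0, sample_sizes=sizes,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, seed=7)


def make_predictors(ds):
    """Single-variable resistance predictors for a synthetic dataset."""
    preds = {"distance": uniform_ibd_predictor(ds.cover, ds.registry)}
    for name, code in ds.class_codes.items():
        surf = parameterize(ds.cover, SurfaceSpec(name, "binary_cover", code))
        preds[name] = resistance_distances(surf, ds.registry)
    preds["slope"] = resistance_distances(
        parameterize(ds.slope, SurfaceSpec("slope", "raw")), ds.registry
    )
    return preds


def single_variable_models(predictors):
    return [CandidateModel(n, [n]) for n in predictors]


@pytest.fixture(scope="session")
def small_predictors(small_dataset):
    return make_predictors(small_dataset)
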