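import numpy as np
import pandas as pd
import pytest

from adsig import preprocessing as pre
from adsig import synthetic as syn


@pytest.fixture(scope="session")
def small_experiment():
    """A 200-gene dye-swap experiment with planted DE, hub and triplet signal."""
    spec = syn.SyntheticCohortSpec(9, 4, 10, n_genes=200, seed=42)
    ids = syn.gene_ids(200)
    signal = syn.PlantedSignal(
        de_genes=((ids[0], 1.0, "up"), (ids[1], 1.0, "down")),
        diffcorr_hubs=((ids[5], 4, 0.9, -0.1),),
        triplet_signature=(ids[10], ids[11], ids[12]),
        triplet_offset=1.5,
        noise_sd=0.3,
    )
    return syn.generate_expression(spec, signal), signal


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    """Subject-collapsed normalized matrix of the small experiment."""
    exp, _ = small_experiment
    matrix, _ = pre.preprocess_experiment(exp.arrays, exp.manifest, collapse="subject_mean")
    return matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def pathology_labels(small_matrix):
    g = small_matrix.groups
    return g.map(lambda x: "A" if x in ("CP-AD", "P-AD") else "B")
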