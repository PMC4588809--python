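import numpy as np
import pytest

import predmet as pm


@pytest.fixture
def effect_table():
    """40/40 samples, 200 features, 10 informative at d=2 (the standard
    recovery scenario), with its ground truth."""
    table, truth = pm.generate_feature_table(
        n_per_class=(40, 40), n_features=200, n_informative=10, effect_size=2.0, seed=11
    )
    return table, truth


@pytest.fixture
def null_table():
    table, truth = pm.generate_feature_table(
        n_per_class=(40, 40), n_features=200, n_informative=0, effect_size=0.0, seed=23
    )
    return table, truth


@pytest.fixture
def labels():
    def _get(table):
        return table.sample_meta["group"].to_numpy()

    return _get


def match_components(features, true_spectra):
    """Assign resolved features to true components by maximal spectral cosine
    (brute force over permutations)."""
    import itertools

    from predmet.resolution import spectral_cosine

    k = len(true_spectra)
    best = None
    for perm in itertools.permutations(range(len(features)), k):
        total = sum(
            spectral_cosine(features[perm[j]].spectrum, true_spectra[j])
            for j in range(k)
        )
        if best is None or total > best[0]:
            best = (total, perm)
    return best[1]


@pytest.fixture
def component_matcher():
    return match_components
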