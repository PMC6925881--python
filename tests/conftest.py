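import dataclasses

import pytest

from spectrocycle import features, preprocess, synth


@pytest.fixture(scope="session")
def clean_dataset():
    """Artefact-free, noise-free, texture-free dataset: the exact forward model."""
    art = synth.Artefacts(
        background_level=0.0,
        vignette_coeffs=(1.0,),
        dead_pixel_rate=0.0,
        saturated_pixel_rate=0.0,
        photon_scale=1000.0,
    )
    cfg = dataclasses.replace(
        synth.DatasetConfig().small(6),
        artefacts=art,
        poisson=False,
        texture_strength=0.0,
    )
    return synth.make_dataset(cfg, seed=101)


@pytest.fixture(scope="session")
def clean_features(clean_dataset):
    return features.build_feature_table(
        clean_dataset.stacks, clean_dataset.masks, clean_dataset.truth)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default artefacts and noise at reduced scale (8 cells per group)."""
    return synth.make_dataset(synth.DatasetConfig().small(8), seed=202)


@pytest.fixture(scope="session")
def prepared_noisy(noisy_dataset):
    stacks, reports = [], []
    for stk, mask in zip(noisy_dataset.stacks, noisy_dataset.masks):
        s, r = preprocess.prepare(stk, background=mask == 0)
        stacks.append(s)
        reports.append(r)
    return stacks, reports


@pytest.fixture(scope="session")
def noisy_features(noisy_dataset, prepared_noisy):
    stacks, _ = prepared_noisy
    return features.build_feature_table(
        stacks, noisy_dataset.masks, noisy_dataset.truth)
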