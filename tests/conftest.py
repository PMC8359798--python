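"""Shared fixtures: one synthetic study cohort, generated once per session.

The cohort mirrors the study structure (7 species, 174 samples, lower-beak
view) at a reduced raster size — 1064x598 originals rescaled by 0.5, which
lands on the same 532x299 working resolution the full-size pipeline uses.
"""

import numpy as np
import pytest

from beakid import pipeline, synthetic

GEN_SIZE = (1064, 598)
RESCALE = 0.5
SEED = 11


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("study_dataset")
    cfg = synthetic.default_study_config(seed=SEED, image_size_px=GEN_SIZE)
    manifest = synthetic.generate_dataset(cfg, root)
    return manifest, root


def _features(study_dataset, descriptor):
    manifest, root = study_dataset
    cfg = pipeline.RunConfig(
        descriptor=descriptor, data_root=str(root), rescale_factor=RESCALE, seed=SEED
    )
    return pipeline.compute_features(cfg, manifest)


@pytest.fixture(scope="session")
def hybrid_features(study_dataset):
    """Colour HOG + MSD features (108 + 10 + label) for the full cohort."""
    return _features(study_dataset, "colour_hog+msd")


@pytest.fixture(scope="session")
def gray_hybrid_features(study_dataset):
    """Grey HOG + MSD features (108 + 10 + label) for the full cohort."""
    return _features(study_dataset, "gray_hog+msd")


@pytest.fixture(scope="session")
def gray_hog_features(gray_hybrid_features):
    """Grey HOG features alone: the hybrid table minus its MSD block."""
    from beakid.shape import MSD_NAMES

    return gray_hybrid_features.drop(columns=list(MSD_NAMES))


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
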