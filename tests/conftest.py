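import numpy as np
import pytest

from stainshift.consensus import derive_label_sets
from stainshift.datamodel import StudyConfig
from stainshift.experiments import cleaned_label_set_for, desk_detector_config
from stainshift.io import monte_carlo_splits
from stainshift.synthgen import generate_study


@pytest.fixture(scope="session")
def small_study():
    """A rendered 12-image study shared by the detector-level tests."""
    config = StudyConfig(n_images=12, rng_seed=11)
    study = generate_study(config, render=True)
    label_sets = derive_label_sets(study)
    label_sets["cleaned_labels"] = cleaned_label_set_for(study, label_sets)
    splits = monte_carlo_splits(study.image_ids, n_splits=2, seed=11)
    return study, label_sets, splits


@pytest.fixture(scope="session")
def trained_tiny(small_study):
    """A single-stain tiny detector trained once and reused."""
    from stainshift.detector import train_detector

    study, label_sets, splits = small_study
    cfg = desk_detector_config("single", seed=11)
    model, history = train_detector(cfg, splits[0], label_sets["he_only_labels"],
                                    study.images)
    return model, history


@pytest.fixture
def rng():
    return np.random.default_rng(123)
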