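import logging
import warnings

import pytest

from verselect.cohort import build_cohort
from verselect.config import CVConfig, GeneratorConfig, PlantedEffect
from verselect.features import extend_variables
from verselect.synthetic import generate_cohort

logging.getLogger("verselect").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with one dominant planted effect (BUN variability)."""
    config = GeneratorConfig(
        n_subjects=400,
        class_ratio=0.15,
        effect_spec=(PlantedEffect("BUN", "S", 2.5),),
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def planted_features(planted_cohort):
    panel, _ = build_cohort(planted_cohort.records)
    return extend_variables(panel)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort: 335 subjects, 33 progressors."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture()
def small_cv():
    return CVConfig(outer_folds=5, inner_folds=3, seed=7)
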