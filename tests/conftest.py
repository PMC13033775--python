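from pathlib import Path

import numpy as np
import pytest

from seedvigor.synthetic import (
    Arm,
    DoseEffect,
    ElongationLaw,
    GrowthModel,
    TreatmentPlan,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_plan():
    """Two arms x 1 dish x 9 seeds, 3 frames on a 900 px tray."""
    return TreatmentPlan(
        arms=(Arm("CTRL"), Arm("DOSE", solution="ZnONPs", concentration=600.0)),
        seeds_per_dish=9,
        replicates=1,
        capture_interval_min=32 * 60,
        duration_h=96.0,
        image_size=(900, 900),
        scale_r=0.1,
    )


@pytest.fixture(scope="session")
def tiny_model():
    return GrowthModel(
        germination_prob=0.8,
        elongation_law=ElongationLaw(max_length_mm=20.0),
        dose_multipliers={"DOSE": DoseEffect(prob=1.2, length=1.3)},
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_plan, tiny_model) -> Path:
    out = tmp_path_factory.mktemp("dataset")
    generate_dataset(tiny_plan, tiny_model, out, master_seed=7, write_images=True)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
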