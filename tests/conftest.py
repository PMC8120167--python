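import numpy as np
import pandas as pd
import pytest

from tsrnomo import reference
from tsrnomo.cutpoint import categorize
from tsrnomo.synthetic import CohortSpec, ImageSpec, generate_cohort, generate_core_image


@pytest.fixture(scope="session")
def core_image_060():
    """Default 512-px synthetic core at 60% stroma with nucleus speckles."""
    spec = ImageSpec(seed=7, true_stroma_frac=0.60, nucleus_density=1.0)
    pixels, truth = generate_core_image(spec)
    return spec, pixels, truth


@pytest.fixture(scope="session")
def core_image_clean():
    """Speckle-free synthetic core at 60% stroma (the clean-accuracy case)."""
    spec = ImageSpec(seed=7, true_stroma_frac=0.60, nucleus_density=0.0)
    pixels, truth = generate_core_image(spec)
    return spec, pixels, truth


@pytest.fixture(scope="session")
def cohort240():
    """Development-cohort-sized synthetic table with the TSR group attached."""
    df = generate_cohort(CohortSpec(n_patients=240, seed=11))
    df["tsr_group"] = categorize(df["tsr"].to_numpy(), reference.TSR_CUTOFF)
    return df


@pytest.fixture(scope="session")
def cohort2000():
    """Large synthetic cohort for parameter-recovery checks."""
    df = generate_cohort(CohortSpec(n_patients=2000, seed=3))
    df["tsr_group"] = categorize(df["tsr"].to_numpy(), reference.TSR_CUTOFF)
    return df


@pytest.fixture(scope="session")
def fitted_results(cohort2000):
    """Cox fit + nomogram on the large cohort (shared to save refits)."""
    from tsrnomo.model import PrognosticModel

    model = PrognosticModel.from_dataframe(
        cohort2000, predictors=["t_stage", "n_status", "grade", "er", "pr", "her2", "tsr_group"]
    )
    return model.fit(selection="enter")
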