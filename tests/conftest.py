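import numpy as np
import pytest

from metasim.calibration import (
    CalibrationInputs,
    fit_colonization_constant,
    fit_growth_rate_constant,
)
from metasim.colonization import ColonizationModel
from metasim.growth import GompertzGrowth

# printed cohort summaries of the two strains
PFP = dict(mean_tumor_weight=1.23, mean_duration=49.9, observed_metastases=788)
RAG2 = dict(mean_tumor_weight=1.16, mean_duration=69.4, observed_metastases=209)

B_CELLS = 4.5e9
X0 = 1e4
ALPHA = 0.663


@pytest.fixture(scope="session")
def pfp_inputs() -> CalibrationInputs:
    return CalibrationInputs(**PFP)


@pytest.fixture(scope="session")
def rag2_inputs() -> CalibrationInputs:
    return CalibrationInputs(**RAG2)


@pytest.fixture(scope="session")
def pfp_growth(pfp_inputs) -> GompertzGrowth:
    a = fit_growth_rate_constant(pfp_inputs)
    return GompertzGrowth.from_start_size(a, B_CELLS, X0)


@pytest.fixture(scope="session")
def rag2_growth(rag2_inputs) -> GompertzGrowth:
    a = fit_growth_rate_constant(rag2_inputs)
    return GompertzGrowth.from_start_size(a, B_CELLS, X0)


@pytest.fixture(scope="session")
def fitted_m(pfp_inputs) -> float:
    return fit_colonization_constant(pfp_inputs)


@pytest.fixture(scope="session")
def colonization_model(fitted_m) -> ColonizationModel:
    return ColonizationModel(m=fitted_m, alpha=ALPHA)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
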