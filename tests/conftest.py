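import numpy as np
import pytest

from gxebias.experiments import (
    CANONICAL_CONTAMINATION,
    SIMULATION_COVARIATES,
    setting_preset,
)
from gxebias.risk_models import (
    ContaminationSpec,
    CovariateDistribution,
    DiseaseModel,
    GenotypeModel,
    RiskCoefficients,
)


@pytest.fixture
def sim_cov() -> CovariateDistribution:
    """The simulation-study covariate law (G 0.10, X 0.14, Z 0.50/0.52)."""
    return SIMULATION_COVARIATES


@pytest.fixture
def no_z_cov() -> CovariateDistribution:
    return CovariateDistribution(
        genotype=GenotypeModel(theta=0.10), env_freq=0.14, covariate_freqs=()
    )


@pytest.fixture
def canonical_contamination() -> ContaminationSpec:
    return CANONICAL_CONTAMINATION


@pytest.fixture
def setting_a_model() -> DiseaseModel:
    return setting_preset("A")["model"]


@pytest.fixture
def setting_b_model() -> DiseaseModel:
    return setting_preset("B")["model"]


def draw_coefficients(rng: np.random.Generator, scale: float = 2.0) -> RiskCoefficients:
    b = rng.uniform(-scale, scale, size=4)
    return RiskCoefficients(*b)


def draw_contamination(rng: np.random.Generator, high: float = 0.5) -> ContaminationSpec:
    return ContaminationSpec(*rng.uniform(0.0, high, size=2))


def draw_trinomial(
    rng: np.random.Generator, scale: float = 2.0, n_z: int = 0
) -> DiseaseModel:
    return DiseaseModel(
        kind="trinomial",
        B=draw_coefficients(rng, scale),
        B_star=draw_coefficients(rng, scale),
        Z_effects=tuple(rng.uniform(-scale, scale, size=n_z)),
    )


def feasible_contamination_model(
    rng: np.random.Generator, n_z: int = 0
) -> DiseaseModel:
    """Random contamination model guaranteed feasible in every cell.

    Keeps the linear predictor low enough that p1 <= 1 - S(x) everywhere.
    """
    while True:
        B = RiskCoefficients(
            beta0=rng.uniform(-2.0, -0.5),
            betaG=rng.uniform(-1.0, 1.0),
            betaX=rng.uniform(-1.0, 1.0),
            betaGxX=rng.uniform(-1.0, 1.0),
        )
        S = draw_contamination(rng, high=0.4)
        z = tuple(rng.uniform(-0.5, 0.5, size=n_z))
        eta_max = (
            B.beta0
            + max(B.betaG, 0)
            + max(B.betaX, 0)
            + max(B.betaGxX, 0)
            + sum(max(v, 0) for v in z)
        )
        p_max = 1.0 / (1.0 + np.exp(-eta_max))
        if p_max < 1.0 - max(S.S0, S.S1) - 0.05:
            return DiseaseModel(
                kind="binary_with_contamination", B=B, Z_effects=z, contamination=S
            )
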