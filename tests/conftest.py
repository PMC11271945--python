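import numpy as np
import pytest
from hypothesis import settings

from renomech import (
    DamageParameters,
    HyperelasticCoefficients,
    MaterialParameters,
    PronySeries,
)
from renomech.materials import default_prony_series, kidney_cortex_parameters

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: reference Yeoh coefficients for kidney cortex (MPa)
TABLE_COEFFS = dict(C10=8.3e-3, C20=0.8, C30=-0.74)


@pytest.fixture(scope="session")
def table_coeffs() -> HyperelasticCoefficients:
    return HyperelasticCoefficients(**TABLE_COEFFS)


@pytest.fixture(scope="session")
def reference_material() -> MaterialParameters:
    return kidney_cortex_parameters()


@pytest.fixture(scope="session")
def two_branch_prony() -> PronySeries:
    return default_prony_series()


@pytest.fixture(scope="session")
def elastic_material(table_coeffs) -> MaterialParameters:
    """No relaxation, no damage: pure near-incompressible hyperelasticity."""
    return MaterialParameters(
        hyperelastic=HyperelasticCoefficients(**TABLE_COEFFS, mu=0.4999),
        damage=DamageParameters(alpha=0.0, beta=0.0, n_exp=2.0),
        prony=PronySeries(m_inf=1.0),
    )


def yeoh_nominal_stress(lam: np.ndarray, C10: float, C20: float, C30: float) -> np.ndarray:
    """Closed-form incompressible uniaxial Yeoh nominal stress oracle.

    sigma_nom = 2 (lam - lam^-2) [C10 + 2 C20 (I1-3) + 3 C30 (I1-3)^2]
    with I1 = lam^2 + 2/lam.
    """
    lam = np.asarray(lam, dtype=float)
    x = lam**2 + 2.0 / lam - 3.0
    return 2.0 * (lam - lam**-2) * (C10 + 2.0 * C20 * x + 3.0 * C30 * x**2)
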