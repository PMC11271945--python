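"""Seeded generator of experiment-like mechanical-test datasets.

Stands in for a raw-data supplement: uniaxial tension at several strain
rates (with between-sample modulus variability, rupture truncation and
measurement noise), ramp-hold relaxation traces, and two-stage confined
("triaxial") compression pressure-volume curves.  Every curve is a pure
function of the recipe and its (condition, sample) indices, so identical
recipes reproduce identical datasets byte for byte.

The confined-compression curves come from a documented *empirical* form --
a linear first stage plus an exponential stiffening stage -- never from the
constitutive model, whose volumetric response does not represent the
fluid-seepage-dominated chamber test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import HyperelasticCoefficients
from .drivers import simulate_relaxation, simulate_uniaxial_tension
from .exceptions import InvalidInputError
from .materials import MaterialParameters, kidney_cortex_parameters

__all__ = [
    "ExperimentRecipe",
    "SampleRecord",
    "SyntheticDataset",
    "rupture_strain_model",
    "generate_tension_dataset",
    "generate_relaxation_dataset",
    "generate_confined_compression_dataset",
    "add_noise",
    "DEFAULT_RUPTURE_ANCHORS",
]

#: Printed mean engineering rupture strains per nominal strain rate (1/s).
DEFAULT_RUPTURE_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.001, 0.218),
    (0.01, 0.189),
    (0.1, 0.172),
)

_KIND_CODES = {"tension": 1, "relaxation": 2, "confined_compression": 3}


@dataclass(frozen=True)
class ExperimentRecipe:
    """Ground truth plus variability knobs for one synthetic campaign.

    Defaults mirror the study conditions: rates 0.001/0.01/0.1 1/s, five
    samples per condition, rupture anchors at the printed means, a 3.0 mm /
    20 min relaxation protocol, and the reference kidney-cortex material.
    """

    material: MaterialParameters = field(default_factory=kidney_cortex_parameters)
    rates: tuple[float, ...] = (0.001, 0.01, 0.1)
    n_samples: int = 5
    modulus_cv: float = 0.05  # lognormal CV on C10/C20/C30, between samples
    noise_level: float = 0.02  # additive noise sd as fraction of peak stress
    rupture_anchors: tuple[tuple[float, float], ...] = DEFAULT_RUPTURE_ANCHORS
    rupture_jitter_sd: float = 0.008
    steps: int = 2000
    seed: int = 0
    # relaxation protocol
    ramp_displacement_mm: float = 3.0
    gauge_length_mm: float = 16.7
    ramp_rate_mm_per_min: float = 100.0
    hold_time_s: float = 1200.0
    # confined-compression empirical form P = a*ev + Pk*(exp(k*(ev-ev0)+) - 1)
    cc_slope_MPa: float = 0.05
    cc_Pk_MPa: float = 0.01
    cc_stiffening_k: float = 30.0
    cc_transition_strain: float = 0.12
    cc_transition_jitter_sd: float = 0.02
    cc_stiffening_jitter_sd: float = 3.0
    cc_max_vol_strain: float = 0.25
    cc_points: int = 200

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise InvalidInputError("need at least one sample per condition")
        for name in ("modulus_cv", "noise_level", "rupture_jitter_sd",
                     "cc_transition_jitter_sd", "cc_stiffening_jitter_sd"):
            if getattr(self, name) < 0.0:
                raise InvalidInputError(f"{name} must be >= 0")

    def rng(self, kind: str, condition_index: int, sample_index: int) -> np.random.Generator:
        """Deterministic per-curve random stream."""
        return np.random.default_rng(
            [self.seed, _KIND_CODES[kind], condition_index, sample_index]
        )

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k not in ("material", "rates", "rupture_anchors")
        }
        d["material"] = self.material.to_dict()
        d["rates"] = list(self.rates)
        d["rupture_anchors"] = [list(a) for a in self.rupture_anchors]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentRecipe":
        d = dict(d)
        material = MaterialParameters.from_dict(d.pop("material"))
        rates = tuple(float(r) for r in d.pop("rates"))
        anchors = tuple((float(a), float(b)) for a, b in d.pop("rupture_anchors"))
        return cls(material=material, rates=rates, rupture_anchors=anchors, **d)


@dataclass
class SampleRecord:
    """One generated curve plus its per-sample ground truth."""

    kind: str
    sample_id: str
    data: pd.DataFrame
    rate: float | None = None
    truth: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    """Generated curves with the embedded generating recipe."""

    records: list[SampleRecord]
    recipe: ExperimentRecipe

    def by_rate(self, rate: float) -> list[SampleRecord]:
        return [r for r in self.records if r.rate == rate]


def rupture_strain_model(rate: float, anchors=DEFAULT_RUPTURE_ANCHORS) -> float:
    """Rupture strain at a given rate: piecewise log-linear in log10(rate).

    Interpolates the mean rupture strain through the anchor points; for
    rates outside [min/10, max*10] an extrapolation warning is issued and
    the nearest anchor value is used.
    """
    rates = np.array([a[0] for a in anchors], dtype=float)
    strains = np.array([a[1] for a in anchors], dtype=float)
    order = np.argsort(rates)
    rates, strains = rates[order], strains[order]
    if rate <= 0.0:
        raise InvalidInputError("rate must be positive")
    if not rates[0] / 10.0 <= rate <= rates[-1] * 10.0:
        warnings.warn(
            f"rate {rate} /s outside the anchored range "
            f"[{rates[0] / 10.0}, {rates[-1] * 10.0}]; using nearest anchor",
            stacklevel=2,
        )
    return float(np.interp(np.log10(rate), np.log10(rates), strains))


def add_noise(values, level: float, rng: np.random.Generator) -> np.ndarray:
    """Add zero-mean Gaussian noise with sd = ``level`` x peak magnitude.

    The independent axis is untouched; ``level=0`` returns the input
    unchanged (and consumes no random numbers in that case is *not*
    guaranteed -- a draw of zeros is still made, keeping streams aligned
    across noise levels).
    """
    y = np.asarray(values, dtype=float)
    if level < 0.0:
        raise InvalidInputError("noise level must be >= 0")
    scale = level * float(np.max(np.abs(y))) if y.size else 0.0
    return y + scale * rng.standard_normal(y.shape)


def _perturbed_material(material: MaterialParameters, cv: float, rng) -> MaterialParameters:
    # one common lognormal stiffness factor on all three Yeoh coefficients:
    # between-sample modulus variability scales the whole stress response
    # while keeping G0 = 2 (C10 + C20 + C30) positive (independent jitter
    # would let the nearly cancelling C20/C30 pair flip its sign)
    f = float(np.exp(cv * rng.standard_normal()))
    h = material.hyperelastic
    hyper = HyperelasticCoefficients(
        C10=h.C10 * f, C20=h.C20 * f, C30=h.C30 * f, mu=h.mu
    )
    return replace(material, hyperelastic=hyper)


def generate_tension_dataset(recipe: ExperimentRecipe) -> SyntheticDataset:
    """Noisy per-sample uniaxial tension curves at each recipe rate."""
    records: list[SampleRecord] = []
    for ri, rate in enumerate(recipe.rates):
        anchor = rupture_strain_model(rate, recipe.rupture_anchors)
        for si in range(recipe.n_samples):
            rng = recipe.rng("tension", ri, si)
            mat = _perturbed_material(recipe.material, recipe.modulus_cv, rng)
            rupture = anchor + recipe.rupture_jitter_sd * float(rng.standard_normal())
            rupture = max(rupture, 0.02)
            curve = simulate_uniaxial_tension(rate, rupture, mat, steps=recipe.steps)
            stress = add_noise(curve.eng_stress_MPa, recipe.noise_level, rng)
            sid = f"tension_r{ri}_s{si}"
            df = pd.DataFrame(
                {
                    "sample_id": sid,
                    "time_s": curve.time_s,
                    "eng_strain": curve.eng_strain,
                    "eng_stress_MPa": stress,
                }
            )
            records.append(
                SampleRecord(
                    kind="tension",
                    sample_id=sid,
                    data=df,
                    rate=rate,
                    truth={
                        "C10": mat.hyperelastic.C10,
                        "C20": mat.hyperelastic.C20,
                        "C30": mat.hyperelastic.C30,
                        "rupture_strain": rupture,
                    },
                )
            )
    return SyntheticDataset(records=records, recipe=recipe)


def generate_relaxation_dataset(recipe: ExperimentRecipe) -> SyntheticDataset:
    """Noisy ramp-hold relaxation traces (3.0 mm step, 20 min hold)."""
    records: list[SampleRecord] = []
    for si in range(recipe.n_samples):
        rng = recipe.rng("relaxation", 0, si)
        mat = _perturbed_material(recipe.material, recipe.modulus_cv, rng)
        curve = simulate_relaxation(
            ramp_displacement=recipe.ramp_displacement_mm,
            gauge_length=recipe.gauge_length_mm,
            ramp_rate=recipe.ramp_rate_mm_per_min,
            hold_time=recipe.hold_time_s,
            params=mat,
            steps=recipe.steps,
        )
        stress = add_noise(curve.eng_stress_MPa, recipe.noise_level, rng)
        sid = f"relaxation_s{si}"
        df = pd.DataFrame(
            {"sample_id": sid, "time_s": curve.time_s, "eng_stress_MPa": stress}
        )
        records.append(SampleRecord(kind="relaxation", sample_id=sid, data=df))
    return SyntheticDataset(records=records, recipe=recipe)


def generate_confined_compression_dataset(recipe: ExperimentRecipe) -> SyntheticDataset:
    """Two-stage empirical pressure-volumetric-strain curves.

    ``P(ev) = a*ev + Pk*(exp(k*max(0, ev - ev0)) - 1)``: a slow linear rise
    until the transition strain ``ev0``, then rapid exponential stiffening;
    ``ev0`` and ``k`` are jittered between samples.
    """
    ev = np.linspace(0.0, recipe.cc_max_vol_strain, recipe.cc_points)
    records: list[SampleRecord] = []
    for si in range(recipe.n_samples):
        rng = recipe.rng("confined_compression", 0, si)
        ev0 = recipe.cc_transition_strain + recipe.cc_transition_jitter_sd * float(
            rng.standard_normal()
        )
        ev0 = min(max(ev0, 0.02), recipe.cc_max_vol_strain * 0.9)
        k = max(recipe.cc_stiffening_k + recipe.cc_stiffening_jitter_sd * float(
            rng.standard_normal()
        ), 1.0)
        pressure = recipe.cc_slope_MPa * ev + recipe.cc_Pk_MPa * (
            np.exp(k * np.maximum(ev - ev0, 0.0)) - 1.0
        )
        pressure = add_noise(pressure, recipe.noise_level, rng)
        sid = f"confined_s{si}"
        df = pd.DataFrame({"sample_id": sid, "vol_strain": ev, "pressure_MPa": pressure})
        records.append(
            SampleRecord(
                kind="confined_compression",
                sample_id=sid,
                data=df,
                truth={"ev0": ev0, "k": k},
            )
        )
    return SyntheticDataset(records=records, recipe=recipe)
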