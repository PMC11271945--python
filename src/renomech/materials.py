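"""Material parameter bundle and its (de)serialization.

``MaterialParameters`` collects everything a material-point driver needs:
Yeoh hyperelastic coefficients, damage-growth constants and the normalized
Prony relaxation spectrum.  ``kidney_cortex_parameters()`` returns the
package's reference parameter set for porcine kidney cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .core import DamageParameters, HyperelasticCoefficients
from .exceptions import ParseError
from .viscoelastic import PronyBranch, PronySeries

__all__ = [
    "MaterialParameters",
    "kidney_cortex_parameters",
    "default_prony_series",
]


@dataclass
class MaterialParameters:
    """Full parameter set of the damage-dependent viscoelastic model."""

    hyperelastic: HyperelasticCoefficients
    damage: DamageParameters = field(default_factory=DamageParameters)
    prony: PronySeries = field(default_factory=lambda: PronySeries(m_inf=1.0))

    def to_dict(self) -> dict:
        return {
            "hyperelastic": {
                "C10": float(self.hyperelastic.C10),
                "C20": float(self.hyperelastic.C20),
                "C30": float(self.hyperelastic.C30),
                "mu": float(self.hyperelastic.mu),
            },
            "damage": {
                "alpha": float(self.damage.alpha),
                "beta": float(self.damage.beta),
                "n_exp": float(self.damage.n_exp),
            },
            "prony": {
                "m_inf": float(self.prony.m_inf),
                "branches": [[float(b.m), float(b.tau)] for b in self.prony.branches],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParameters":
        try:
            hyper = HyperelasticCoefficients(**d["hyperelastic"])
            damage = DamageParameters(**d["damage"])
            prony = PronySeries(
                m_inf=float(d["prony"]["m_inf"]),
                branches=tuple(
                    PronyBranch(float(m), float(tau))
                    for m, tau in d["prony"]["branches"]
                ),
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed material-parameter mapping: {exc}") from exc
        return cls(hyperelastic=hyper, damage=damage, prony=prony)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MaterialParameters":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_prony_series() -> PronySeries:
    """Reference two-branch relaxation spectrum for kidney cortex.

    Chosen so the normalized hold-phase stress decays fast over the first
    few seconds, is essentially flat past ~200 s, and the forward model
    reproduces the observed spread of ultimate tensile strength across
    strain rates 0.001-0.1 1/s.
    """
    return PronySeries(
        m_inf=0.20,
        branches=(PronyBranch(0.45, 3.0), PronyBranch(0.35, 40.0)),
    )


def kidney_cortex_parameters(
    prony: PronySeries | None = None,
    mu: float = 0.495,
) -> MaterialParameters:
    """Reference calibrated parameter set for porcine kidney cortex.

    C10 = 8.3e-3, C20 = 0.8, C30 = -0.74 MPa; beta = 3.0e-4, n = 2.0,
    alpha = 0 (pressure sensitivity not separately identified in tension).
    """
    return MaterialParameters(
        hyperelastic=HyperelasticCoefficients(C10=8.3e-3, C20=0.8, C30=-0.74, mu=mu),
        damage=DamageParameters(alpha=0.0, beta=3.0e-4, n_exp=2.0),
        prony=prony if prony is not None else default_prony_series(),
    )
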