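"""Model/Results interface to the two calibration stages.

`PronyRelaxationModel` fits the normalized relaxation spectrum to a
dimensionless decay; `TensionCalibrationModel` fits the hyperelastic and
damage constants to tension stress-strain data by replaying the forward
material-point driver inside a least-squares loop.  Both follow the
familiar fit-returns-results pattern: the model object holds the data and
options, ``.fit()`` returns a results object carrying the estimates,
residual diagnostics and a ``summary()`` table, and prediction hangs off
the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    CalibrationConfig,
    CalibrationResult,
    TensionCurve,
    correct_for_ramp,
    fit_prony,
    fit_tension,
    goodness_of_fit,
    normalize_relaxation,
    predict_rates,
)
from .exceptions import InvalidInputError, ParseError
from .materials import MaterialParameters
from .viscoelastic import PronySeries, relaxation_function

__all__ = [
    "PronyRelaxationModel",
    "PronyRelaxationResults",
    "TensionCalibrationModel",
    "TensionCalibrationResults",
]


class PronyRelaxationModel:
    """Prony-series model of a dimensionless relaxation decay.

    Parameters
    ----------
    time_s, values
        Samples of the normalized relaxation function (first value ~ 1 at
        t = 0).
    n_branches
        Number of Maxwell branches (default 2).
    """

    def __init__(self, time_s, values, n_branches: int = 2, ramp_time: float = 0.0):
        self.time_s = np.asarray(time_s, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.n_branches = int(n_branches)
        self.ramp_time = float(ramp_time)

    @classmethod
    def from_stress_trace(cls, time_s, stress_MPa, n_branches: int = 2):
        """Build from a raw relaxation stress trace.

        Normalizes the hold phase at the stress peak and records the time
        to the peak as the loading-ramp duration, which ``fit`` uses for
        the half-ramp correction of the spectrum.
        """
        t_arr = np.asarray(time_s, dtype=float)
        y_arr = np.asarray(stress_MPa, dtype=float)
        t, m = normalize_relaxation(t_arr, y_arr)
        ramp_time = float(t_arr[int(np.argmax(y_arr))] - t_arr[0])
        return cls(t, m, n_branches=n_branches, ramp_time=ramp_time)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col="time_s", stress_col="eng_stress_MPa",
        n_branches: int = 2,
    ):
        return cls.from_stress_trace(df[time_col], df[stress_col], n_branches=n_branches)

    def fit(self) -> "PronyRelaxationResults":
        hold_series, rmse = fit_prony(self.time_s, self.values, self.n_branches)
        series = (
            correct_for_ramp(hold_series, self.ramp_time)
            if self.ramp_time > 0.0
            else hold_series
        )
        return PronyRelaxationResults(
            model=self, series=series, rmse=rmse, hold_series=hold_series
        )


@dataclass
class PronyRelaxationResults:
    """Fitted spectrum.  ``series`` is the material spectrum (ramp-corrected
    when the model knows its ramp duration); ``hold_series`` is the raw fit
    to the normalized hold-phase samples."""

    model: PronyRelaxationModel
    series: PronySeries
    rmse: float
    hold_series: PronySeries | None = None

    @property
    def fittedvalues(self) -> np.ndarray:
        return relaxation_function(
            self.model.time_s, self.hold_series or self.series
        )

    @property
    def resid(self) -> np.ndarray:
        return self.model.values - self.fittedvalues

    def summary(self) -> str:
        lines = [
            "Prony relaxation fit",
            "=" * 44,
            f"{'nobs':<24}{self.model.time_s.size:>20}",
            f"{'branches':<24}{len(self.series.branches):>20}",
            f"{'m_inf':<24}{self.series.m_inf:>20.6g}",
        ]
        for i, b in enumerate(self.series.branches, start=1):
            lines.append(f"{f'm_{i}':<24}{b.m:>20.6g}")
            lines.append(f"{f'tau_{i} (s)':<24}{b.tau:>20.6g}")
        lines.append(f"{'RMSE':<24}{self.rmse:>20.3e}")
        lines.append("=" * 44)
        return "\n".join(lines)


class TensionCalibrationModel:
    """Damage-dependent viscoelastic model fitted to tension data.

    Holds the tension curves, the (fixed) Prony spectrum from the
    relaxation stage and the calibration options; ``fit`` dispatches to the
    staged least-squares protocol.
    """

    def __init__(
        self,
        curves: list[TensionCurve],
        prony: PronySeries,
        config: CalibrationConfig | None = None,
    ):
        if not curves:
            raise InvalidInputError("no tension curves supplied")
        self.curves = list(curves)
        self.prony = prony
        self.config = config or CalibrationConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        prony: PronySeries,
        config: CalibrationConfig | None = None,
    ):
        """Build from a long-format table.

        Requires columns ``sample_id, eng_strain, eng_stress_MPa`` and
        either ``rate_per_s`` or ``time_s`` (the nominal rate is then the
        final strain over the final time, per sample).
        """
        needed = {"sample_id", "eng_strain", "eng_stress_MPa"}
        if not needed <= set(df.columns):
            raise ParseError(f"dataframe must contain columns {sorted(needed)}")
        curves = []
        for sid, g in df.groupby("sample_id", sort=True):
            if "rate_per_s" in g.columns:
                rate = float(g["rate_per_s"].iloc[0])
            elif "time_s" in g.columns and g["time_s"].iloc[-1] > 0:
                rate = float(g["eng_strain"].iloc[-1] / g["time_s"].iloc[-1])
            else:
                raise ParseError("cannot infer strain rate: need rate_per_s or time_s")
            curves.append(
                TensionCurve(
                    eng_strain=g["eng_strain"].to_numpy(dtype=float),
                    eng_stress_MPa=g["eng_stress_MPa"].to_numpy(dtype=float),
                    rate=rate,
                    sample_id=str(sid),
                )
            )
        return cls(curves, prony, config)

    def fit(
        self, vary: str = "alternating", start: MaterialParameters | None = None
    ) -> "TensionCalibrationResults":
        result = fit_tension(
            self.curves, self.prony, self.config, vary=vary, start=start
        )
        return TensionCalibrationResults(model=self, result=result)


@dataclass
class TensionCalibrationResults:
    model: TensionCalibrationModel
    result: CalibrationResult
    extra_diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> MaterialParameters:
        return self.result.material

    @property
    def rmse_MPa(self) -> dict[float, float]:
        return self.result.rmse_MPa

    def predict(self, rates, max_strains, steps: int | None = None):
        """Forward tension curves at new rates from the single fitted set."""
        return predict_rates(self.result, rates, max_strains, steps=steps)

    def score_against(self, curve) -> tuple[float, float]:
        """RMSE / relative RMSE of the calibrated model against a curve."""
        rate = curve.rate if getattr(curve, "rate", None) else min(
            c.rate for c in self.model.curves
        )
        sim = predict_rates(self.result, [rate], [float(np.max(curve.eng_strain))])[0]
        return goodness_of_fit(curve, sim)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Tension calibration (staged least squares)",
            "=" * 52,
            f"{'C10 (MPa)':<24}{r.hyperelastic.C10:>24.6g}",
            f"{'C20 (MPa)':<24}{r.hyperelastic.C20:>24.6g}",
            f"{'C30 (MPa)':<24}{r.hyperelastic.C30:>24.6g}",
            f"{'mu (fixed)':<24}{r.hyperelastic.mu:>24.6g}",
            f"{'G0 (MPa)':<24}{r.hyperelastic.G0:>24.6g}",
            f"{'K0 (MPa)':<24}{r.hyperelastic.K0:>24.6g}",
            f"{'alpha (1/MPa)':<24}{r.damage.alpha:>24.6g}",
            f"{'beta':<24}{r.damage.beta:>24.6g}",
            f"{'n':<24}{r.damage.n_exp:>24.6g}",
            f"{'Prony m_inf (fixed)':<24}{r.prony.m_inf:>24.6g}",
        ]
        for rate, rmse in sorted(r.rmse_MPa.items()):
            lines.append(f"{f'RMSE @ {rate:g}/s (MPa)':<24}{rmse:>24.3e}")
        for meta in r.convergence:
            lines.append(
                f"stage {meta['stage']:<14} cost={meta['cost']:.3e} "
                f"nfev={meta['nfev']}" + ("  [at bounds]" if meta["at_bounds"] else "")
            )
        lines.append("=" * 52)
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the fitted parameters and diagnostics to YAML."""
        payload = {
            "material": self.params.to_dict(),
            "rmse_MPa": {float(k): float(v) for k, v in self.result.rmse_MPa.items()},
            "convergence": self.result.convergence,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @staticmethod
    def load_material(path) -> MaterialParameters:
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        key = "material" if "material" in payload else None
        return MaterialParameters.from_dict(payload[key] if key else payload)
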