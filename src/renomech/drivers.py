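"""Material-point drivers replaying uniaxial tension and relaxation tests.

Both protocols are axial-stretch-controlled uniaxial stress states: the
axial stretch follows a prescribed path and the two (equal) lateral
stretches are solved at every step so that the *total* viscoelastic lateral
stress vanishes.  The hereditary convolution is advanced with the recursive
exponential update, and the damage variable is integrated in a staggered
fashion (the void fraction from the end of the previous step is used while
solving the current step's kinematics).

Output curves report engineering (first Piola-Kirchhoff) axial stress,
``J * sigma_axial / lambda_axial``, against engineering strain
``lambda_axial - 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .core import (
    OCTAHEDRAL_PREFACTOR,
    damage_growth_increment,
)
from .exceptions import DamageValidityWarning, IntegrationError, InvalidInputError
from .materials import MaterialParameters
from .viscoelastic import step_weights

__all__ = [
    "LoadingProgram",
    "SimulatedCurve",
    "simulate_program",
    "simulate_uniaxial_tension",
    "simulate_relaxation",
]

#: Default number of time steps per driver run.
DEFAULT_STEPS = 2000

_NEWTON_MAX_ITER = 60


@dataclass(frozen=True)
class LoadingProgram:
    """Axial-stretch-controlled loading path on an explicit time grid."""

    times: np.ndarray
    stretch: Callable[[float], float]
    label: str = "custom"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise InvalidInputError("time grid must be a 1-D array with >= 1 point")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0.0):
            raise InvalidInputError("time grid must start at 0 and strictly increase")
        if abs(self.stretch(0.0) - 1.0) > 1e-12:
            raise InvalidInputError("stretch path must start at 1 (undeformed)")
        object.__setattr__(self, "times", t)

    @classmethod
    def constant_rate(
        cls, rate: float, max_eng_strain: float, steps: int = DEFAULT_STEPS
    ) -> "LoadingProgram":
        """Constant engineering-strain-rate ramp to ``max_eng_strain``."""
        if rate <= 0.0:
            raise InvalidInputError(f"strain rate must be positive, got {rate}")
        if max_eng_strain < 0.0:
            raise InvalidInputError("max_eng_strain must be >= 0")
        if max_eng_strain == 0.0:
            return cls(times=np.array([0.0]), stretch=lambda t: 1.0, label="tension")
        t_end = max_eng_strain / rate
        times = np.linspace(0.0, t_end, steps + 1)
        return cls(times=times, stretch=lambda t: 1.0 + rate * t, label="tension")

    @classmethod
    def ramp_hold(
        cls,
        target_strain: float,
        ramp_time: float,
        hold_time: float,
        steps: int = DEFAULT_STEPS,
    ) -> "LoadingProgram":
        """Linear ramp to ``target_strain`` in ``ramp_time`` s, then hold."""
        if ramp_time <= 0.0 or hold_time < 0.0 or target_strain <= 0.0:
            raise InvalidInputError("ramp_hold needs positive target strain and times")
        n_ramp = max(25, steps // 20)
        n_hold = max(steps - n_ramp, 1)
        times = np.concatenate(
            [
                np.linspace(0.0, ramp_time, n_ramp + 1),
                ramp_time + np.linspace(0.0, hold_time, n_hold + 1)[1:],
            ]
        )

        def stretch(t: float) -> float:
            return 1.0 + target_strain * min(t / ramp_time, 1.0)

        return cls(times=times, stretch=stretch, label="relaxation")


@dataclass
class SimulatedCurve:
    """Sampled output of a material-point driver."""

    time_s: np.ndarray
    eng_strain: np.ndarray
    eng_stress_MPa: np.ndarray
    damage_c: np.ndarray
    Je: np.ndarray
    kind: str = "tension"
    rate: float | None = None
    truncated: bool = False
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "eng_strain": self.eng_strain,
                "eng_stress_MPa": self.eng_stress_MPa,
                "damage_c": self.damage_c,
                "Je": self.Je,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")


def _elastic_uniaxial(lam1: float, lam2: float, c: float, C10, C20, C30, K):
    """Elastic lateral/axial deviatoric Cauchy stresses and pressure.

    Scalar fast path equivalent to composing ``compute_invariants``,
    ``elastic_deviatoric_stress`` and ``elastic_pressure`` for a
    transversely symmetric state (lam2 = lam3).  Returns
    (s_axial, s_lateral, pressure, J, I1_bar, I2_bar, phi).
    """
    J = lam1 * lam2 * lam2
    Jm23 = J ** (-2.0 / 3.0)
    a1 = lam1 * lam1 * Jm23
    a2 = lam2 * lam2 * Jm23
    I1 = a1 + 2.0 * a2
    I2 = 2.0 * a1 * a2 + a2 * a2
    x = I1 - 3.0
    dpsi = C10 + 2.0 * C20 * x + 3.0 * C30 * x * x
    phi = 1.0 + math.log1p(-c)
    pref = phi * (2.0 / J) * dpsi
    s1 = pref * (a1 - I1 / 3.0)
    s2 = pref * (a2 - I1 / 3.0)
    Je = J / (1.0 + c)
    p = K * (Je - 1.0) / (1.0 + c)
    return s1, s2, p, J, I1, I2, phi


def simulate_program(
    program: LoadingProgram,
    params: MaterialParameters,
    octahedral_prefactor: float = OCTAHEDRAL_PREFACTOR,
) -> SimulatedCurve:
    """Integrate the constitutive model along an axial-stretch programme."""
    hyper = params.hyperelastic
    C10, C20, C30, K = hyper.C10, hyper.C20, hyper.C30, hyper.K0
    dmg = params.damage
    series = params.prony
    nb = len(series.branches)

    times = program.times
    n = times.size
    eng_strain = np.empty(n)
    eng_stress = np.empty(n)
    damage_c = np.empty(n)
    Je_arr = np.empty(n)
    eng_strain[0] = 0.0
    eng_stress[0] = 0.0
    damage_c[0] = 0.0
    Je_arr[0] = 1.0

    # hereditary internal variables (driver-local bookkeeping mirrors
    # viscoelastic.hereditary_step; kept scalar/ndarray for speed)
    h_dev = np.zeros((nb, 3))
    h_p = np.zeros(nb)
    prev_dev = np.zeros(3)
    prev_p = 0.0

    c = 0.0
    Igamma_prev = 0.0
    lam2 = 1.0
    truncated = False
    tol_f = 1e-12 * max(1.0, K)

    k_stop = n
    for k in range(1, n):
        dt = times[k] - times[k - 1]
        lam1 = program.stretch(times[k])
        decay, coef, A = step_weights(series, dt)
        # history offset of the lateral total stress (independent of lam2)
        C_hist = float((decay * h_dev[:, 1]).sum() - coef.sum() * prev_dev[1]) + float(
            (decay * h_p).sum() - coef.sum() * prev_p
        )

        def residual(l2: float) -> float:
            _, s2, p, _, _, _, _ = _elastic_uniaxial(lam1, l2, c, C10, C20, C30, K)
            return A * (s2 + p) + C_hist

        lam2 = _solve_lateral(residual, lam2, tol_f, times[k])

        s1, s2, p, J, I1, I2, _ = _elastic_uniaxial(lam1, lam2, c, C10, C20, C30, K)
        new_dev = np.array([s1, s2, s2])
        h_dev = decay[:, None] * h_dev + coef[:, None] * (new_dev - prev_dev)[None, :]
        h_p = decay * h_p + coef * (p - prev_p)
        prev_dev = new_dev
        prev_p = p
        sigma_axial = series.m_inf * s1 + float(h_dev[:, 0].sum()) + (
            series.m_inf * p + float(h_p.sum())
        )

        # staggered damage update from the converged kinematics
        radicand = max(2.0 * I1 * I1 - 6.0 * I2, 0.0)
        Igamma = octahedral_prefactor * math.sqrt(radicand)
        c += damage_growth_increment(Igamma_prev, Igamma, p, dmg)
        Igamma_prev = Igamma

        eng_strain[k] = lam1 - 1.0
        eng_stress[k] = J * sigma_axial / lam1
        damage_c[k] = c
        Je_arr[k] = J / (1.0 + c)

        if c >= 1.0 or 1.0 + math.log1p(-min(c, 1.0 - 1e-300)) <= 0.0:
            warnings.warn(
                f"damage softening factor non-positive at t={times[k]:.4g} s "
                f"(c={c:.4g}); curve truncated",
                DamageValidityWarning,
                stacklevel=2,
            )
            truncated = True
            k_stop = k + 1
            break

    sl = slice(0, k_stop)
    return SimulatedCurve(
        time_s=times[sl].copy(),
        eng_strain=eng_strain[sl],
        eng_stress_MPa=eng_stress[sl],
        damage_c=damage_c[sl],
        Je=Je_arr[sl],
        kind=program.label,
        truncated=truncated,
    )


def _solve_lateral(residual, lam2_init: float, tol_f: float, t: float) -> float:
    """Find the lateral stretch zeroing the total lateral stress.

    Newton/secant iteration warm-started from the previous step, with a
    bisection fallback on a bracket expanded around the initial guess.
    """
    l0 = lam2_init
    f0 = residual(l0)
    if abs(f0) <= tol_f:
        return l0
    l1 = l0 * (1.0 - 1e-6) if f0 > 0.0 else l0 * (1.0 + 1e-6)
    f1 = residual(l1)
    for _ in range(_NEWTON_MAX_ITER):
        if abs(f1) <= tol_f:
            return l1
        denom = f1 - f0
        if denom == 0.0:
            break
        l2 = l1 - f1 * (l1 - l0) / denom
        if not (0.05 <= l2 <= 20.0):
            break
        l0, f0, l1, f1 = l1, f1, l2, residual(l2)
        if abs(l1 - l0) < 1e-14 * l1:
            return l1
    # bracket + bisection fallback
    lo, hi = lam2_init * 0.5, lam2_init * 2.0
    flo, fhi = residual(lo), residual(hi)
    for _ in range(60):
        if flo * fhi <= 0.0:
            break
        lo *= 0.7
        hi *= 1.4
        flo, fhi = residual(lo), residual(hi)
    else:
        raise IntegrationError(
            f"lateral stress-free solve failed to bracket a root at t={t:.4g} s"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = residual(mid)
        if abs(fmid) <= tol_f or hi - lo < 1e-15 * mid:
            return mid
        if flo * fmid <= 0.0:
            hi, fhi = mid, fmid
        else:
            lo, flo = mid, fmid
    raise IntegrationError(f"lateral stress-free solve did not converge at t={t:.4g} s")


def simulate_uniaxial_tension(
    rate: float,
    max_eng_strain: float,
    params: MaterialParameters,
    steps: int = DEFAULT_STEPS,
) -> SimulatedCurve:
    """Constant engineering-strain-rate uniaxial tension to ``max_eng_strain``.

    Engineering strain grows as ``rate * t``; the lateral faces are
    traction-free.  Returns the engineering stress-strain curve together
    with the damage and elastic-volume traces.
    """
    program = LoadingProgram.constant_rate(rate, max_eng_strain, steps)
    curve = simulate_program(program, params)
    curve.rate = rate
    curve.kind = "tension"
    return curve


def simulate_relaxation(
    ramp_displacement: float = 3.0,
    gauge_length: float = 16.7,
    ramp_rate: float = 100.0,
    hold_time: float = 1200.0,
    params: MaterialParameters = None,
    steps: int = DEFAULT_STEPS,
) -> SimulatedCurve:
    """Ramp-and-hold relaxation test driver.

    Displacement (mm) is applied at ``ramp_rate`` (mm/min) over a gauge
    length (mm), then held for ``hold_time`` s.  Defaults mirror the
    reference protocol: 3.0 mm step on a 16.7 mm gauge held for 20 min.
    """
    if params is None:
        raise InvalidInputError("params is required")
    if min(ramp_displacement, gauge_length, ramp_rate, hold_time) <= 0.0:
        raise InvalidInputError("geometry, rate and times must be positive")
    target_strain = ramp_displacement / gauge_length
    ramp_time = ramp_displacement / (ramp_rate / 60.0)
    program = LoadingProgram.ramp_hold(target_strain, ramp_time, hold_time, steps)
    curve = simulate_program(program, params)
    curve.kind = "relaxation"
    curve.metadata.update(
        ramp_time_s=ramp_time, target_strain=target_strain, hold_time_s=hold_time
    )
    return curve
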