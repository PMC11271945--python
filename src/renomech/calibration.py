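"""Two-stage least-squares identification of the material parameters.

Stage one fits the normalized Prony relaxation spectrum to hold-phase
relaxation data (a separable variable-projection fit: non-negative weights
by NNLS inside a nonlinear search over the relaxation times).  Stage two
fits the Yeoh coefficients -- and, in a complementary stage, the damage
constants -- by minimizing squared engineering-stress residuals between the
forward uniaxial driver and the lowest-rate tension curve.  Cross-rate
prediction then re-runs the forward model at other rates with the single
calibrated set, without re-fitting.

The pressure-sensitivity exponent ``alpha`` is held at 0 by default: in
tension the pressure stays small before damage matters, which makes
``alpha`` practically unidentifiable from tension data alone; fitting it
can be enabled via :class:`CalibrationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, nnls

from .core import DamageParameters, HyperelasticCoefficients
from .drivers import DEFAULT_STEPS, SimulatedCurve, simulate_uniaxial_tension
from .exceptions import FitError, InvalidInputError
from .materials import MaterialParameters
from .viscoelastic import PronySeries

__all__ = [
    "TensionCurve",
    "CalibrationConfig",
    "CalibrationResult",
    "normalize_relaxation",
    "fit_prony",
    "correct_for_ramp",
    "refine_prony_forward",
    "fit_tension",
    "predict_rates",
    "goodness_of_fit",
    "average_curves",
]


@dataclass(frozen=True)
class TensionCurve:
    """One tension stress-strain record tagged with its nominal rate."""

    eng_strain: np.ndarray
    eng_stress_MPa: np.ndarray
    rate: float
    sample_id: str = "s0"

    def __post_init__(self) -> None:
        s = np.asarray(self.eng_strain, dtype=float)
        y = np.asarray(self.eng_stress_MPa, dtype=float)
        if s.shape != y.shape or s.ndim != 1:
            raise InvalidInputError("strain and stress must be 1-D arrays of equal length")
        if np.any(np.diff(s) <= 0.0):
            raise InvalidInputError("engineering strain must be strictly increasing")
        object.__setattr__(self, "eng_strain", s)
        object.__setattr__(self, "eng_stress_MPa", y)


@dataclass
class CalibrationConfig:
    """Options of the tension-calibration protocol."""

    steps: int = DEFAULT_STEPS
    mu: float = 0.495
    fit_alpha: bool = False
    alpha_fixed: float = 0.0
    n_rounds: int = 2  # alternating-stage rounds when vary="alternating"
    c10_bounds: tuple[float, float] = (1e-6, 10.0)
    c20_bounds: tuple[float, float] = (-10.0, 10.0)
    c30_bounds: tuple[float, float] = (-10.0, 10.0)
    log10_beta_bounds: tuple[float, float] = (-8.0, -1.0)
    n_exp_bounds: tuple[float, float] = (0.5, 5.0)
    max_nfev: int = 200


@dataclass
class CalibrationResult:
    """Fitted parameters with residual diagnostics and convergence metadata."""

    hyperelastic: HyperelasticCoefficients
    damage: DamageParameters
    prony: PronySeries
    rmse_MPa: dict[float, float] = field(default_factory=dict)
    convergence: list[dict] = field(default_factory=list)
    config: CalibrationConfig = field(default_factory=CalibrationConfig)

    @property
    def material(self) -> MaterialParameters:
        return MaterialParameters(
            hyperelastic=self.hyperelastic, damage=self.damage, prony=self.prony
        )


def normalize_relaxation(time_s, stress_MPa) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a relaxation stress trace to a dimensionless decay.

    The hold phase is taken to start at the stress peak; hold stresses are
    divided by the peak so the first normalized sample equals 1, and times
    are re-zeroed at the peak.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(stress_MPa, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidInputError("time and stress must be 1-D arrays of equal length")
    k0 = int(np.argmax(y))
    peak = y[k0]
    if peak <= 0.0:
        raise InvalidInputError("relaxation trace has a non-positive peak stress")
    if t.size - k0 < 5:
        raise InvalidInputError("need at least 5 post-peak samples to normalize")
    return t[k0:] - t[k0], y[k0:] / peak


def _prony_design(t: np.ndarray, taus: np.ndarray) -> np.ndarray:
    # columns exp(-t/tau) - 1 so that m(t) - 1 = X @ weights with
    # m_inf = 1 - sum(weights) eliminated
    return np.exp(-t[:, None] / taus[None, :]) - 1.0


def fit_prony(time_s, samples, n_branches: int = 2) -> tuple[PronySeries, float]:
    """Fit a normalized Prony series to dimensionless relaxation samples.

    Variable projection: for trial relaxation times the weights solve a
    non-negative least-squares problem with the normalization
    ``m_inf = 1 - sum(m_i)`` eliminated; the times are then optimized in
    log-space.  Returns the series and the fit RMSE.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(samples, dtype=float)
    if n_branches < 1:
        raise InvalidInputError("need at least one Prony branch")
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidInputError("time and samples must be 1-D arrays of equal length")
    if t.size <= 2 * n_branches + 1:
        raise InvalidInputError(
            f"{t.size} samples cannot constrain {2 * n_branches} Prony parameters"
        )
    rhs = y - 1.0
    # initial times log-spaced over [1, 300] s (hold-phase decay window)
    log_tau0 = np.linspace(0.0, math.log10(300.0), n_branches)

    def weights_for(log_tau: np.ndarray) -> np.ndarray:
        X = _prony_design(t, 10.0**log_tau)
        w, _ = nnls(X, rhs)
        return w

    def resid(log_tau: np.ndarray) -> np.ndarray:
        X = _prony_design(t, 10.0**log_tau)
        w, _ = nnls(X, rhs)
        return X @ w - rhs

    sol = least_squares(
        resid,
        log_tau0,
        bounds=(-2.0, 4.0),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=500,
    )
    if not sol.success:
        raise FitError(f"Prony time search failed: {sol.message}")
    w = weights_for(sol.x)
    taus = 10.0**sol.x
    total = float(w.sum())
    if total > 1.0 + 1e-8:
        raise FitError("fitted Prony weights exceed the normalization bound")
    m_inf = max(1.0 - total, 0.0)
    # merge numerically coincident times so the series stays well-ordered
    order = np.argsort(taus)
    taus, w = taus[order], w[order]
    keep_t: list[float] = []
    keep_w: list[float] = []
    for tau_i, w_i in zip(taus, w):
        if keep_t and tau_i <= keep_t[-1] * (1.0 + 1e-9):
            keep_w[-1] += w_i
            keep_t[-1] = max(keep_t[-1], tau_i * (1.0 + 1e-12))
        else:
            keep_t.append(float(tau_i))
            keep_w.append(float(w_i))
    series = PronySeries.from_weights(m_inf, keep_w, keep_t)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return series, rmse


def correct_for_ramp(series: PronySeries, ramp_time: float) -> PronySeries:
    """Ramp correction of a Prony series fitted to normalized hold data.

    For a loading ramp of duration ``T`` with an (approximately) linear
    elastic-stress history, the hold-phase stress normalized at the end of
    the ramp decays like ``(m_inf + sum u_i exp(-t/tau_i)) /
    (m_inf + sum u_i)`` with ``u_i = m_i g_i`` and
    ``g_i = (tau_i/T)(1 - exp(-T/tau_i)) < 1``: the plain fit sees the fast
    branches under-weighted.  This inverts the reweighting
    (``m_i ~ u_i / g_i``) and renormalizes, recovering the true spectrum up
    to the nonlinearity of the stress ramp.
    """
    if ramp_time < 0.0:
        raise InvalidInputError("ramp duration must be >= 0")
    if not series.branches or ramp_time == 0.0:
        return series
    x = ramp_time / series.taus
    g = np.where(x > 1e-8, -np.expm1(-x) / np.maximum(x, 1e-300), 1.0 - 0.5 * x)
    w = series.weights / g
    total = series.m_inf + float(w.sum())
    return PronySeries.from_weights(series.m_inf / total, w / total, series.taus)


def refine_prony_forward(
    time_hold,
    m_samples,
    material: MaterialParameters,
    *,
    ramp_displacement: float = 3.0,
    gauge_length: float = 16.7,
    ramp_rate: float = 100.0,
    hold_time: float = 1200.0,
    n_branches: int = 2,
    steps: int = 600,
    start: PronySeries | None = None,
    max_points: int = 80,
) -> PronySeries:
    """Refine a Prony spectrum by forward-modelling the ramp-hold protocol.

    The closed-form ramp correction assumes a linear elastic-stress ramp;
    for a strongly nonlinear stress-strain response the residual bias can
    reach a few percent of the spectrum.  This stage removes it by least-
    squares matching of the *simulated* normalized hold decay (driver run
    of the actual protocol with trial spectra) to the measured one.  The
    material's hyperelastic/damage constants only shape the ramp, so a
    preliminary estimate of them is sufficient.
    """
    from dataclasses import replace as _replace

    from .drivers import simulate_relaxation

    t = np.asarray(time_hold, dtype=float)
    y = np.asarray(m_samples, dtype=float)
    if t.size > max_points:
        idx = np.unique(np.linspace(0, t.size - 1, max_points).astype(int))
        t, y = t[idx], y[idx]
    nb = int(n_branches)
    if start is not None and len(start.branches) == nb:
        x0 = np.concatenate([start.weights, np.log10(start.taus)])
    else:
        x0 = np.concatenate(
            [np.full(nb, 0.5 / nb), np.linspace(0.0, math.log10(300.0), nb)]
        )

    def build(x) -> PronySeries | None:
        w = np.clip(x[:nb], 0.0, 1.0)
        taus = np.sort(10.0 ** x[nb:])
        if w.sum() > 0.999 or np.any(taus[1:] / taus[:-1] < 1.05):
            return None
        return PronySeries.from_weights(1.0 - w.sum(), w, taus)

    def resid(x) -> np.ndarray:
        series = build(x)
        if series is None:
            return np.full(t.size, 10.0)
        sim = simulate_relaxation(
            ramp_displacement=ramp_displacement,
            gauge_length=gauge_length,
            ramp_rate=ramp_rate,
            hold_time=hold_time,
            params=_replace(material, prony=series),
            steps=steps,
        )
        tt, mm = normalize_relaxation(sim.time_s, sim.eng_stress_MPa)
        return np.interp(t, tt, mm) - y

    sol = least_squares(
        resid,
        x0,
        bounds=([0.0] * nb + [-2.0] * nb, [1.0] * nb + [4.0] * nb),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=300,
    )
    series = build(sol.x)
    if not sol.success or series is None:
        raise FitError(f"forward Prony refinement failed: {sol.message}")
    return series


def average_curves(curves: list[TensionCurve]) -> TensionCurve:
    """Average same-rate curves onto the strain grid of the shortest one."""
    if not curves:
        raise InvalidInputError("no curves to average")
    if len(curves) == 1:
        return curves[0]
    shortest = min(curves, key=lambda c: c.eng_strain[-1])
    grid = shortest.eng_strain
    stacked = np.vstack(
        [np.interp(grid, c.eng_strain, c.eng_stress_MPa) for c in curves]
    )
    return TensionCurve(
        eng_strain=grid,
        eng_stress_MPa=stacked.mean(axis=0),
        rate=curves[0].rate,
        sample_id="mean",
    )


def _initial_c10(curve: TensionCurve, mu: float) -> float:
    """Starting C10 from the initial slope via E0 = 2 (1 + mu) G0, C10 = G0/2."""
    s, y = curve.eng_strain, curve.eng_stress_MPa
    k = max(2, min(s.size // 10, 20))
    slope = float(np.polyfit(s[:k], y[:k], 1)[0])
    E0 = max(slope, 1e-6)
    G0 = E0 / (2.0 * (1.0 + mu))
    return max(G0 / 2.0, 1e-5)


def fit_tension(
    curves: list[TensionCurve],
    prony: PronySeries,
    config: CalibrationConfig | None = None,
    *,
    vary: str = "alternating",
    start: MaterialParameters | None = None,
) -> CalibrationResult:
    """Least-squares fit of the constitutive constants to tension data.

    Parameters
    ----------
    curves
        Tension records; same-rate samples are averaged and the lowest-rate
        group is the calibration target.
    prony
        Normalized relaxation spectrum from the relaxation stage (held
        fixed here).
    vary : {"hyperelastic", "damage", "alternating"}
        Which parameter group to optimize.  ``"hyperelastic"`` fits
        (C10, C20, C30) with the damage constants frozen at their ``start``
        values; ``"damage"`` fits (beta, n) with the Yeoh coefficients
        frozen; ``"alternating"`` cycles both stages ``config.n_rounds``
        times.
    start
        Initial (and, for the frozen group, fixed) parameter values.  When
        omitted, C10 comes from the initial slope of the data, C20 = C30
        = 0, beta = 1e-4, n = 2, alpha = ``config.alpha_fixed``.
    """
    config = config or CalibrationConfig()
    if vary not in ("hyperelastic", "damage", "alternating"):
        raise InvalidInputError(f"unknown vary mode {vary!r}")
    if not curves:
        raise InvalidInputError("no tension curves supplied")
    by_rate: dict[float, list[TensionCurve]] = {}
    for c in curves:
        by_rate.setdefault(c.rate, []).append(c)
    cal_rate = min(by_rate)
    target = average_curves(by_rate[cal_rate])
    if target.eng_strain[-1] - target.eng_strain[0] <= 0.0 or target.eng_strain.size < 5:
        raise InvalidInputError("calibration curve has an empty strain range")

    if start is None:
        start = MaterialParameters(
            hyperelastic=HyperelasticCoefficients(
                C10=_initial_c10(target, config.mu), C20=0.0, C30=0.0, mu=config.mu
            ),
            damage=DamageParameters(alpha=config.alpha_fixed, beta=1e-4, n_exp=2.0),
            prony=prony,
        )

    data_strain = target.eng_strain
    data_stress = target.eng_stress_MPa
    max_strain = float(data_strain[-1])

    def forward(hyper: HyperelasticCoefficients, damage: DamageParameters) -> np.ndarray:
        params = MaterialParameters(hyperelastic=hyper, damage=damage, prony=prony)
        sim = simulate_uniaxial_tension(cal_rate, max_strain, params, steps=config.steps)
        return np.interp(data_strain, sim.eng_strain, sim.eng_stress_MPa)

    hyper = replace(start.hyperelastic, mu=config.mu)
    damage = start.damage
    convergence: list[dict] = []

    def run_hyper_stage(hyper, damage):
        def resid(x):
            h = HyperelasticCoefficients(C10=x[0], C20=x[1], C30=x[2], mu=config.mu)
            return forward(h, damage) - data_stress

        lo = [config.c10_bounds[0], config.c20_bounds[0], config.c30_bounds[0]]
        hi = [config.c10_bounds[1], config.c20_bounds[1], config.c30_bounds[1]]
        sol = least_squares(
            resid,
            [hyper.C10, hyper.C20, hyper.C30],
            bounds=(lo, hi),
            x_scale=[1e-2, 1.0, 1.0],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=config.max_nfev,
        )
        _check(sol, "hyperelastic")
        convergence.append(_meta("hyperelastic", sol))
        return HyperelasticCoefficients(
            C10=float(sol.x[0]), C20=float(sol.x[1]), C30=float(sol.x[2]), mu=config.mu
        )

    def run_damage_stage(hyper, damage):
        def resid(x):
            d = DamageParameters(alpha=damage.alpha, beta=10.0 ** x[0], n_exp=x[1])
            return forward(hyper, d) - data_stress

        x0 = [math.log10(max(damage.beta, 10.0 ** config.log10_beta_bounds[0])), damage.n_exp]
        sol = least_squares(
            resid,
            x0,
            bounds=(
                [config.log10_beta_bounds[0], config.n_exp_bounds[0]],
                [config.log10_beta_bounds[1], config.n_exp_bounds[1]],
            ),
            diff_step=1e-4,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=config.max_nfev,
        )
        _check(sol, "damage")
        convergence.append(_meta("damage", sol))
        return DamageParameters(
            alpha=damage.alpha, beta=float(10.0 ** sol.x[0]), n_exp=float(sol.x[1])
        )

    if vary == "hyperelastic":
        hyper = run_hyper_stage(hyper, damage)
    elif vary == "damage":
        damage = run_damage_stage(hyper, damage)
    else:
        for _ in range(config.n_rounds):
            hyper = run_hyper_stage(hyper, damage)
            damage = run_damage_stage(hyper, damage)

    final = forward(hyper, damage)
    rmse = float(np.sqrt(np.mean((final - data_stress) ** 2)))
    return CalibrationResult(
        hyperelastic=hyper,
        damage=damage,
        prony=prony,
        rmse_MPa={cal_rate: rmse},
        convergence=convergence,
        config=config,
    )


def _check(sol, stage: str) -> None:
    if not sol.success:
        raise FitError(f"{stage} stage failed to converge: {sol.message}")


def _meta(stage: str, sol) -> dict:
    at_bounds = bool(np.any(sol.active_mask != 0))
    return {
        "stage": stage,
        "cost": float(sol.cost),
        "nfev": int(sol.nfev),
        "status": int(sol.status),
        "message": str(sol.message),
        "at_bounds": at_bounds,
    }


def predict_rates(
    result: CalibrationResult,
    rates,
    max_strains,
    steps: int | None = None,
) -> list[SimulatedCurve]:
    """Forward-simulate tension at the requested rates with the fitted set.

    No re-fitting takes place: each curve is a genuine prediction from the
    single calibrated parameter set (damage is re-integrated per rate).
    """
    steps = steps if steps is not None else result.config.steps
    return [
        simulate_uniaxial_tension(r, ms, result.material, steps=steps)
        for r, ms in zip(rates, max_strains, strict=True)
    ]


def goodness_of_fit(curve_a, curve_b) -> tuple[float, float]:
    """RMSE (MPa) and peak-relative RMSE between two stress-strain curves.

    Accepts :class:`SimulatedCurve`, :class:`TensionCurve` or
    ``(strain, stress)`` pairs; curve b is interpolated onto curve a's
    strains within the overlapping range.
    """
    sa, ya = _as_xy(curve_a)
    sb, yb = _as_xy(curve_b)
    lo = max(sa[0], sb[0])
    hi = min(sa[-1], sb[-1])
    if hi <= lo:
        raise InvalidInputError("curves have disjoint strain ranges")
    mask = (sa >= lo) & (sa <= hi)
    grid = sa[mask]
    diff = np.interp(grid, sb, yb) - ya[mask]
    rmse = float(np.sqrt(np.mean(diff**2)))
    peak = float(np.max(np.abs(ya[mask])))
    return rmse, rmse / peak if peak > 0.0 else math.inf


def _as_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, SimulatedCurve):
        return curve.eng_strain, curve.eng_stress_MPa
    if isinstance(curve, TensionCurve):
        return curve.eng_strain, curve.eng_stress_MPa
    x, y = curve
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)
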