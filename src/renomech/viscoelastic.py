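"""Prony-series relaxation and recursive evaluation of hereditary integrals.

The viscoelastic stress is a fading-memory convolution of the elastic-stress
rate with a dimensionless relaxation function

    m(t) = m_inf + sum_i m_i * exp(-t / tau_i),        m(0) = 1,

shared by the deviatoric and volumetric responses.  The convolution

    S(t) = int_0^t m(t - xi) dS_e/dxi dxi

is advanced with the standard per-branch exponential recurrence (Herrmann &
Peterson / Taylor): each branch keeps an internal stress ``h_i`` updated as

    h_i(t+dt) = exp(-dt/tau_i) h_i(t)
                + m_i (tau_i/dt) (1 - exp(-dt/tau_i)) (S_e(t+dt) - S_e(t)),

which is exact whenever the elastic stress varies linearly within the step
and costs O(steps) overall.  The total stress is
``m_inf * S_e + sum_i h_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "PronyBranch",
    "PronySeries",
    "HereditaryState",
    "relaxation_function",
    "shear_relaxation_modulus",
    "step_weights",
    "hereditary_step",
]


@dataclass(frozen=True)
class PronyBranch:
    """One Maxwell branch: dimensionless weight and relaxation time (s)."""

    m: float
    tau: float


@dataclass(frozen=True)
class PronySeries:
    """Normalized Prony series ``m(t) = m_inf + sum m_i exp(-t/tau_i)``.

    Normalization ``m_inf + sum m_i = 1`` makes ``m(0) = 1``, so the
    instantaneous moduli equal the initial ones (``G(0) = G0``).
    """

    m_inf: float
    branches: tuple[PronyBranch, ...] = ()

    def __post_init__(self) -> None:
        if self.m_inf < 0.0:
            raise ConfigurationError(f"m_inf must be >= 0, got {self.m_inf}")
        taus = [b.tau for b in self.branches]
        if any(b.m < 0.0 for b in self.branches):
            raise ConfigurationError("all branch weights must be >= 0")
        if any(t <= 0.0 for t in taus):
            raise ConfigurationError("all relaxation times must be > 0")
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ConfigurationError("relaxation times must be strictly increasing")
        total = self.m_inf + sum(b.m for b in self.branches)
        if abs(total - 1.0) > 1e-8:
            raise ConfigurationError(
                f"Prony series not normalized: m_inf + sum(m_i) = {total}, expected 1"
            )

    @classmethod
    def from_weights(cls, m_inf: float, weights, taus) -> "PronySeries":
        order = np.argsort(np.asarray(taus, dtype=float))
        branches = tuple(
            PronyBranch(float(np.asarray(weights, dtype=float)[i]), float(np.asarray(taus, dtype=float)[i]))
            for i in order
        )
        return cls(m_inf=float(m_inf), branches=branches)

    @property
    def weights(self) -> np.ndarray:
        return np.array([b.m for b in self.branches])

    @property
    def taus(self) -> np.ndarray:
        return np.array([b.tau for b in self.branches])


def relaxation_function(t, series: PronySeries):
    """Dimensionless relaxation function ``m(t)``; accepts scalars or arrays."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise InvalidInputError("relaxation function defined for t >= 0 only")
    out = np.full_like(t_arr, series.m_inf, dtype=float)
    for b in series.branches:
        out = out + b.m * np.exp(-t_arr / b.tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def shear_relaxation_modulus(t, series: PronySeries, G0: float):
    """Shear relaxation modulus ``G(t) = G0 * m(t)`` (MPa)."""
    return G0 * relaxation_function(t, series)


@dataclass
class HereditaryState:
    """Internal variables of the recursive convolution.

    ``h_dev`` has shape (n_branches, 3) -- one accumulator per branch per
    principal deviatoric component; ``h_p`` has shape (n_branches,) for the
    pressure.  All accumulators are zero at t = 0.
    """

    series: PronySeries
    h_dev: np.ndarray = field(default=None)  # type: ignore[assignment]
    h_p: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_dev: np.ndarray = field(default_factory=lambda: np.zeros(3))
    prev_p: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        nb = len(self.series.branches)
        if self.h_dev is None:
            self.h_dev = np.zeros((nb, 3))
        if self.h_p is None:
            self.h_p = np.zeros(nb)


def step_weights(series: PronySeries, dt: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-branch decay and increment weights for a step of length ``dt``.

    Returns ``(decay, coef, A)`` where ``decay_i = exp(-dt/tau_i)``,
    ``coef_i = m_i (tau_i/dt)(1 - decay_i)`` and
    ``A = m_inf + sum coef_i`` is the multiplier of the *current* elastic
    stress in the updated total -- the quantity a driver needs to linearize
    its stress-free solve.
    """
    if dt <= 0.0:
        raise InvalidInputError(f"dt must be positive, got {dt}")
    taus = series.taus
    weights = series.weights
    if taus.size == 0:
        return np.empty(0), np.empty(0), series.m_inf
    x = dt / taus
    decay = np.exp(-x)
    # (1 - exp(-x))/x, stable for small x
    coef = weights * np.where(x > 1e-8, (1.0 - decay) / np.maximum(x, 1e-300), 1.0 - 0.5 * x)
    A = series.m_inf + float(coef.sum())
    return decay, coef, A


def hereditary_step(
    state: HereditaryState,
    new_dev,
    new_p: float,
    dt: float,
) -> tuple[HereditaryState, np.ndarray, float]:
    """Advance the convolution by ``dt`` given the new elastic stresses.

    Parameters
    ----------
    state : HereditaryState
        State at the beginning of the step.
    new_dev : array-like, shape (3,)
        Elastic deviatoric principal stresses at the end of the step (MPa).
    new_p : float
        Elastic pressure at the end of the step (MPa).

    Returns
    -------
    (new_state, total_dev, total_p)
        Updated state plus the total (viscoelastic) deviatoric components
        and pressure at the end of the step.
    """
    new_dev = np.asarray(new_dev, dtype=float)
    decay, coef, _ = step_weights(state.series, dt)
    d_dev = new_dev - state.prev_dev
    d_p = new_p - state.prev_p
    h_dev = decay[:, None] * state.h_dev + coef[:, None] * d_dev[None, :]
    h_p = decay * state.h_p + coef * d_p
    total_dev = state.series.m_inf * new_dev + h_dev.sum(axis=0)
    total_p = state.series.m_inf * new_p + float(h_p.sum())
    new_state = replace(
        state,
        h_dev=h_dev,
        h_p=h_p,
        prev_dev=new_dev.copy(),
        prev_p=new_p,
        t=state.t + dt,
    )
    return new_state, total_dev, total_p
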