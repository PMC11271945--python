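# Methods

`renomech` implements a damage-dependent finite-strain viscoelastic
constitutive model for soft renal tissue at a single material point, the
two-stage least-squares procedure that calibrates it to uniaxial tension
and ramp-hold relaxation data, and a seeded generator of experiment-like
datasets for validating that procedure end to end. This note records the
model, the numerical choices, and the limits of what the synthetic
experiments can demonstrate.

## Constitutive model

**Elastic response.** The strain energy splits additively into a
distortional and a volumetric part,

    W = phi(c) * omega(I1b) + (K/2) (Je - 1)^2,
    omega = C10 (I1b - 3) + C20 (I1b - 3)^2 + C30 (I1b - 3)^3,

with `I1b` the first invariant of the isochoric right Cauchy-Green tensor
`Cb = J^(-2/3) C`, `J` the total volume ratio, and `Je = J / (1 + c)` the
elastic volume ratio. The scalar `c` is a void volume fraction that tracks
damage-produced (or fluid-loss) volume; it softens only the distortional
response, through `phi(c) = 1 + ln(1 - c)`, and carries no elastic
pressure (the pressure is `K (Je - 1) / (1 + c)`, the derivative of the
volumetric energy through `Je(J)` at frozen `c`).

Although `omega` is written in the Yeoh (I1-only) form, the deviatoric
stress is evaluated in principal axes,

    s_i = phi(c) * (2/J) * d(omega)/d(I1b) * (lb_i^2 - I1b/3),

where `lb_i` are the isochoric principal stretches; the three components
are traceless by construction.

**Viscoelasticity.** Shear and bulk relax with the same normalized Prony
series `m(t) = m_inf + sum_i m_i exp(-t/tau_i)`, `m(0) = 1`, applied as a
hereditary convolution of the elastic-stress rate. The convolution acts on
the principal Cauchy deviator and the pressure; all protocols of interest
(tension, ramp-hold relaxation, confined compression) are coaxial, so
principal axes are fixed and no objective-rate machinery is needed.
Linearity of the convolution preserves the traceless character of the
deviator. The initial shear modulus is `G0 = 2 (C10 + C20 + C30)`; Young's
and bulk moduli follow from `E = 2 (1 + mu) G` and
`K = 2 G (1 + mu) / (3 (1 - 2 mu))` with the Poisson ratio fixed at
`mu = 0.495` (initially incompressible tissue). The precise value of `K0`
is immaterial as long as the material stays effectively incompressible
before damage grows; `mu` is configuration, not a fitted parameter.

**Damage growth.** The void fraction evolves as

    dc/dt = (d gamma/dt) * exp(alpha * P),     gamma = beta * Igamma^n,

driven by the octahedral shear strain
`Igamma = (1/6) sqrt(2 I1b^2 - 6 I2b)`. The radicand equals
`sum_{i<j} (lb_i^2 - lb_j^2)^2` and is convention-free; the 1/6 prefactor
is the package default and is exposed as an argument because it only
rescales `beta` (a 1/3 convention is selectable). Increments are clipped
at zero so damage never heals; with `alpha = 0` the integrated `c(t)`
equals `beta * Igamma(t)^n` exactly on monotone paths, which serves as a
closed-form oracle for the integrator. `phi` is physical only for small
`c`; a validity warning fires when `c > 1 - exp(-1)` (negative `phi`) and
drivers truncate the curve there.

## Time integration

The convolution is advanced by the per-branch exponential recurrence

    h_i(t+dt) = exp(-dt/tau_i) h_i(t)
                + m_i (tau_i/dt)(1 - exp(-dt/tau_i)) * dS_e,

exact for elastic-stress histories that are linear within a step and O(N)
overall. Total stress is `m_inf * S_e + sum_i h_i`. Uniaxial stress states
are enforced by solving, at every step, for the lateral stretch that zeroes
the *total* lateral stress (secant/Newton iteration warm-started from the
previous step, residual tolerance 1e-12 x max(1, K) MPa, bisection
fallback); because the recurrence is affine in the current elastic stress,
the solve needs only a scalar residual. Damage is updated in a staggered
fashion: the void fraction from the previous step enters the current
step's stress evaluation, and the increment is computed from the converged
kinematics. Default resolution is 2000 steps per driver run; halving the
step changes the final stress by well under 0.2%, and the driver reduces
to the closed-form incompressible Yeoh nominal stress
`2 (lam - lam^-2) d(omega)/d(I1b)` to better than 0.5% when relaxation and
damage are switched off and `mu -> 0.5`.

Engineering conventions throughout: engineering strain is elongation over
initial gauge length; engineering stress is force over initial area, i.e.
the axial first Piola-Kirchhoff component `J sigma_axial / lambda_axial`.

## Calibration

Stage one fits the normalized relaxation spectrum. The hold phase of a
relaxation trace is normalized at the stress peak, and the Prony series is
fitted by variable projection: non-negative weights solve an NNLS problem
(with `m_inf = 1 - sum m_i` eliminated) inside a nonlinear search over
log-spaced relaxation times. Two branches are the default, with initial
times spread over 1-300 s (the observed decay is essentially complete by
200 s). Because the ramp to the hold displacement takes finite time
(default protocol: 3.0 mm at 100 mm/min on a 16.7 mm gauge, i.e. 1.8 s,
then a 1200 s hold), the normalized data are not exactly `m(t)`: assuming
a linear stress ramp, branch weights appear multiplied by
`g_i = (tau_i/T)(1 - exp(-T/tau_i))`, which `correct_for_ramp` inverts in
closed form. The residual bias of the linear-ramp assumption (the true
stress ramp is strongly nonlinear) is removed, when desired, by
`refine_prony_forward`: a least-squares re-fit in which each trial
spectrum is pushed through the actual ramp-hold driver. In the pipeline
this refinement runs after a preliminary tension fit (the hyperelastic
constants only shape the ramp, so a few-percent-accurate estimate
suffices) and reduces the spectrum error from a few percent to ~0.1%.

Stage two fits the constitutive constants to the lowest-rate tension
curve by trust-region least squares on engineering-stress residuals, with
the forward driver inside the loop. Same-rate samples are averaged first;
residual weighting is uniform over strain samples. A simultaneous free fit
of all six constants on one curve is ill-posed, so the protocol is staged:
(C10, C20, C30) with the damage pair frozen, (beta, n) with the Yeoh
coefficients frozen (beta is searched in log10 space), or the two stages
alternating. Initial guesses: C10 from the initial slope via
`E0 = 2 (1 + mu) G0` and `C10 = G0/2`, `C20 = C30 = 0`, `beta = 1e-4`,
`n = 2`; bounds `C10 > 0`, `n` in [0.5, 5], `log10 beta` in [-8, -1].
`alpha` is held at 0 by default: before damage matters the tension
pressure is small, making `alpha` practically unidentifiable from tension
data alone (fitting it is opt-in). With the reference parameter set the
damage term perturbs the tension curve by only ~1e-5 relative, so a blind
joint fit leaves (beta, n) wherever they started while the Yeoh
coefficients absorb the difference; the staged protocol with the
complementary group frozen recovers every constant from noise-free
synthetic data essentially exactly. Cross-rate prediction re-runs the
forward model at the other rates with the single calibrated set —
including re-integrating damage per rate — with no re-fitting.

## Synthetic experiments

The generator emulates the study conditions: tension at 0.001/0.01/0.1 1/s
with five samples per rate, a 3.0 mm / 20 min relaxation protocol, and
two-stage confined-compression pressure-volume curves. Reference material
constants are `C10 = 8.3e-3`, `C20 = 0.8`, `C30 = -0.74` MPa,
`beta = 3.0e-4`, `n = 2.0`, `alpha = 0`. The relaxation spectrum is not
identified numerically anywhere in the source material, so the package
ships a documented default, `m_inf = 0.20` with branches (0.45, 3 s) and
(0.35, 40 s), chosen so that (i) the normalized decay is fast over the
first seconds and essentially flat past 200 s, and (ii) the forward
model's ultimate tensile strengths across the three rates
(~0.056/0.075/0.096 MPa at the anchored rupture strains) approximate the
reported means (0.0395/0.0599/0.0914 MPa) and in particular their
roughly 2.3x spread across rates, which an `m_inf` of 0.35 cannot
produce. Rupture strains follow a piecewise log-linear model through the
anchors (0.001, 0.218), (0.01, 0.189), (0.1, 0.172) — decreasing in rate —
with Gaussian per-sample jitter.

Between-sample variability multiplies all three Yeoh coefficients by a
single lognormal stiffness factor (CV 5% by default): one common factor,
rather than independent jitter, because `C20 ~ 0.8` and `C30 ~ -0.74`
nearly cancel in `G0 = 2 (C10 + C20 + C30)` and independent perturbation
routinely drives the initial shear modulus negative. Within-curve noise is
additive zero-mean Gaussian with standard deviation a fraction (2%
default) of each curve's peak stress. Every curve is generated from a
dedicated `default_rng([seed, kind, condition, sample])` stream, so a
recipe reproduces its dataset byte for byte.

The confined-compression curves use a documented empirical form,
`P = a ev + Pk (exp(k (ev - ev0)+) - 1)` with per-sample jitter on the
transition strain `ev0` and stiffening rate `k` — deliberately *not* the
constitutive model, whose solid-phase volumetric law does not represent
the fluid-seepage-dominated chamber response. Defaults (`a = 0.05` MPa,
`Pk = 0.01` MPa, `k = 30`, `ev0 = 0.12`, up to `ev = 0.25`) give a slow
first stage and a rapid stiffening stage reaching ~0.5 MPa.

**What passing tests do and do not show.** The synthetic data inherit the
forward model's structure, so parameter-recovery results demonstrate that
the calibration machinery is correct and well-conditioned — not that the
model describes real kidney cortex. Real tissue adds inter-animal
heterogeneity, anisotropy, preconditioning and moisture effects,
non-Gaussian and correlated measurement noise, and rupture physics, none
of which the generator represents; rupture here is a truncation point, not
a prediction.

## Known limitations

- Principal-axis implementation only: no shear-dominated or rotating
  deformation paths, no finite-element boundary-value problems.
- The model has no failure criterion; curves end at the imposed rupture
  strain (generator) or imposed maximum strain (driver).
- `phi(c) = 1 + ln(1 - c)` is physical only for small void fractions;
  drivers warn and truncate once `phi <= 0`.
- The damage constants are identifiable from tension data only with the
  hyperelastic group fixed (or vice versa); joint blind identification
  from a single curve is not supported by the data and is not claimed.
- Isotropic, isothermal, single-phase solid: no poroelastic fluid flow,
  although the damage variable can be read as a fluid-loss volume.
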