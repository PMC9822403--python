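# Methods

## Relaxation model

The package models ¹H relaxation in neat oils as driven by the
intramolecular dipole–dipole interaction between neighbouring protons,
modulated by isotropic rotational tumbling with a single correlation
time τc (BPP theory). The implemented rate expressions are the
canonical spectral-density forms

    1/T1 = (3/10) K [ τc/(1+ω₀²τc²) + 4τc/(1+4ω₀²τc²) ]
    1/T2 = (3/20) K [ 3τc + 5τc/(1+ω₀²τc²) + 2τc/(1+4ω₀²τc²) ]

with K = (μ₀/4π)²γ⁴ℏ²/l⁶. These are the only forms consistent with the
three qualitative facts the model must reproduce: T1 = T2 in the
fast-motion limit, T2 monotonically decreasing while T1 passes through
a minimum (at ω₀τc ≈ 0.616) as motion slows, and T1 ≥ T2 everywhere.
The T1/T2 ratio depends only on x = ω₀τc, so a measured ratio inverts
to a correlation time without knowledge of the interproton distance;
the inversion is done by Brent's method on the monotone branch with a
relative tolerance of 1e-12 and a default bracket of [1e-13, 1e-5] s,
wide enough for small molecules through polymeric aggregates at 23 MHz.
A ratio of exactly 1 is mapped to the lower bracket, since below
ω₀τc ≈ 1e-2 the ratio no longer identifies τc.

Defaults: Larmor frequency 23 MHz (ω₀ = 2πf applied exactly once, at
parameter construction); interproton distance l = 1.79 Å, a typical
geminal ¹H–¹H separation, overridable, as is the combined prefactor K.
The linear fast-motion law R2 = c·M2·τc is exposed separately with the
conventional constant c = 10 configurable, because conventions differ
on which numerical factors are folded into the second moment M2; it is
only a small-ω₀τc approximation and is never used where the full
expression applies. Intermolecular and translational-diffusion
contributions to relaxation are not modeled.

## Hydrodynamics

Molecules are treated as hydrodynamic spheres: tumbling rate
1/τc = 3kT/(4πηr³), Stokes–Einstein–Debye time τc = C_r·ηV/(kT), and
rotational diffusion D_r = kT/(8πηR³), mutually consistent for
spherical volumes (τc·D_r = 1/6 for C_r = 1). C_r defaults to 1 and is
documented as an empirical fit parameter. Self-diffusion of unentangled
chains scales as M_w^(-α) with α = 1 below the entanglement coupling
molecular weight M_wc; M_wc defaults to infinity (no entanglement) as
the oils of interest are far below it. Viscosity crosses the API
boundary in centipoise — matching how oil tables are reported — and is
converted to SI internally; the conversions are single correctly
rounded floating-point operations, so a round trip is exact to at most
one ulp.

## CPMG fitting

Echo trains are fit with a single exponential A(t) = M0·exp(-t/T2).
The default route warm-starts Levenberg–Marquardt least squares with an
ordinary-least-squares fit of log amplitude on time; the log-linear
route is also exposed on its own. Because the log transform amplifies
tail noise, echoes below three times the estimated tail-noise floor
(the standard deviation of the last 10% of echoes) are excluded from
the log-linear stage only — the nonlinear stage always uses every echo.
Fits that return T2 ≤ 0 or T2 > 1e6 ms (no measurable decay within any
plausible acquisition) raise a fit-failure error rather than a value.
Rates follow the convention R2[s⁻¹] = 1000/T2[ms]. The reference
table's rate column is treated as s⁻¹ throughout: its values equal
1000/T2[ms] row by row, so its printed ms⁻¹ header is recorded as a
unit typo. Multi-exponential decays are out of scope here; mixtures
are handled by the 2-D inversion below.

## T1-T2 map inversion

IR-CPMG data D[i,k] = Σⱼ wⱼ(1-2e^(-τᵢ/T1ⱼ))e^(-tₖ/T2ⱼ) are inverted
onto log-spaced (T1, T2) grids (default 64×64 over 0.1–10⁴ ms, covering
every oil in the bundled tables) by Tikhonov-regularized nonnegative
least squares,

    min_{F≥0} ‖K1 F K2ᵀ − D‖² + λ‖F‖².

The exponential kernels are first compressed by truncated SVD (singular
values below 1e-8 of the largest are dropped; numerical rank ≈ 10 per
kernel, so the compression is essentially lossless) and the problem is
solved by monotone FISTA — accelerated projected gradient with a 1/L
step in which a candidate step is only accepted when it does not
increase the objective, so the objective history is non-increasing by
construction. Iteration stops when the relative objective decrease
falls below 1e-9 (cap 200 000 iterations; hitting the cap raises a
diagnostic error carrying the residual). On a 1-CPU machine a 64×64
inversion takes a few seconds. The solution was cross-checked against
an independent active-set solver (Lawson–Hanson NNLS on the explicit
Kronecker system): objectives agree to ~1e-6 relative on a 32×32 test
problem.

λ defaults to 1e-2, suited to the high-SNR synthetic data used
throughout; smaller values sharpen noiseless inversions. Peaks are the
per-blob maxima of the connected components above 2% of the map
maximum, with blob-integrated mass, sorted by descending mass — so
well-separated components keep their relative weights even when
regularization smears them.

An inversion-recovery (1 − 2e^(-τ/T1)) encoding kernel is assumed, the
convention for benchtop instruments; perfect inversion pulses are
assumed too, so real data with imperfect inversion efficiency would
need the factor 2 relaxed.

Classification of peaks follows two thresholds: T2 < 10 ms marks
high-viscosity/saturated species, T1/T2 > 2 marks aggregates/slowed
rotation, and everything else is free fluid. The 10 ms boundary is the
conventional dividing line for viscous polyols; the ratio cutoff of 2
is a design choice — any value comfortably above the near-diagonal
smear of the inversion and below genuine aggregate ratios works, and it
is configurable. The gel diagnostic flags rigid-network formation when
the dominant peak's T2 moves by less than 10% while T1 grows by more
than 50%, the signature of a network that immobilises only a small mass
fraction while most molecules keep tumbling. Solid-fat crystallisation
physics beyond this qualitative diagnostic is out of scope.

## Chain-length calibration

CL is regressed on R2/η by ordinary least squares over the liquid
records of the bundled 17-oil panel. The fitted coefficients are
slope +52.998 CL/(s⁻¹cp⁻¹) and intercept −1.5597. The slope is
positive — chain length rises with R2/η across the panel — and the
reference equation's printed negative slope magnitude is recorded as a
sign erratum (its magnitude, and the intercept, match the refit to
printed precision). The predictor is the viscosity-normalised rate,
not raw R2: only R2/η reproduces the reference coefficients, and the
normalisation is what removes the solvent-friction factor from τc.
Predictions report the real-valued CL, its nearest integer (ties
rounded away from zero), and an extrapolation flag outside the training
range of R2/η ≈ 0.063–0.499; the calibration's validity range is
CL 3–24, and general vegetable oils with longer chains extrapolate.
Solid fats have no viscosity and are excluded from fitting (prediction
for them is possible but extrapolative). Leave-one-out refits quantify
per-oil accuracy: LOO RMSE ≈ 1.7 carbons against ≈ 1.5 in-sample. The
bundled tables carry one known conflict between their two sources for
ketal glycerol (formula C7H12ClN3O2 / CL 7 in the calibration panel vs
C6H12O3 / CL 6 in the inventory); the calibration panel is reproduced
verbatim and wins for fitting.

## Synthetic data

The generator emulates the benchtop acquisition the reference data were
taken with: 23 MHz, echo time 0.3 ms, 1000 echoes, 16 scans, 250 kHz
sampling, 10 s repetition delay. Decays are mono-exponential per oil
(matching the single-exponential analysis of the reference panel;
multi-component truth is available through explicit component lists),
with additive Gaussian noise on echo magnitudes, default σ = 0.5% of
M0 — a stated convention reflecting the high SNR of 16 averaged scans
on neat oil, not a measured instrument figure. All randomness flows
from explicit integer seeds; identical seeds give bit-identical output.

Two precision conventions matter. Generating a single train by oil name
uses the tabulated T2 verbatim (so a noiseless tributyrin train fits
back to exactly 325 ms). Generating the full calibration panel instead
derives each truth T2 from the tabulated rate column (T2 = 1000/R2),
which carries ~6 significant digits against the T2 column's 2–4; with
the rounded T2 column the noiseless pipeline closure lands ~1% off the
reference slope purely from table rounding, while the rate-derived
truth reproduces it to printed precision. T1 values, absent from the
reference panel, default to T1 = T2 (the fast-motion equality that
holds for these free fluids) and are overridable per component.

What the generator does not emulate: B1 inhomogeneity, stimulated
echoes, baseline drift, temperature variation, phase noise, or
multi-exponential character within a single named oil. Passing tests
therefore demonstrate correctness of the estimators and the inversion
under the stated noise model, not robustness to instrument artifacts.

## Problem sizes and numerical choices

Test and example problem sizes are chosen to exercise the estimators at
realistic acquisition dimensions while keeping a full run fast on one
CPU: 1000-echo trains, 200-replicate Monte-Carlo checks of estimator
bias, 16 inversion delays × 500–1000 echoes for map inversions on
64×64 grids (32×32 for the solver cross-check). Monotonicity and
round-trip invariants are checked on dense log grids (10³–2×10⁵
points). Degenerate inputs fail loudly and specifically: constant
echo trains, sub-unity T1/T2 ratios, components with T1 < T2,
non-positive physical quantities, zero-variance calibration predictors
and empty maps all raise typed errors with actionable messages.
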