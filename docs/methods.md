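# Methods

## Scope and units

Energies are kcal/mol, entropies kcal/mol/K, temperatures kelvin
(Celsius only at the CLI/file boundary), distances Å.  The gas constant
is R = 1.9872×10⁻³ kcal/mol/K.  Rates are reported *relative* to an
Eyring reference point by default — the transition-state-theory
prefactor C in k = C·T·exp(-ΔG‡/RT) cancels in every fit and every
ratio the analysis uses; an absolute mode with C = kB/h is available.

## Thermokinetics

Arrhenius decomposition regresses ΔG‡/T on 1/T; the slope is ΔH‡ and the
intercept -ΔS‡.  When standard errors accompany the barriers the fit is
weighted by 1/sem² (propagated to ΔG‡/T); it is unweighted otherwise.
Whether the original analysis weighted its regressions is not knowable
from the published material, so both modes are exposed and the weighted
one is the default in the presence of errors.

The piecewise fit searches every interior breakpoint that leaves at
least three points per segment (the breakpoint temperature is shared by
both segments).  A break is *accepted* only when the single-line
weighted residual sum of squares exceeds a configurable factor (default
4×) times the two-segment one.  The published break was judged visually;
the factor-of-4 rule is this package's reproducible stand-in, and on the
exact two-state model curve it places the break at 298 K, i.e. at the
population crossover.

## Kinetic models

Both models are evaluated in the log domain (`log1p`/`logaddexp`) so
that extreme equilibrium constants cannot overflow.  The apparent heat
capacity of the two-state model is implemented from the closed form

    ΔCp‡app = -ΔHeq² Φ(1-Φ) / (R T²),  Φ = Keq/(1+Keq),

which is the exact temperature derivative of ΔH‡app = ΔH3‡ - Φ·ΔHeq;
the tests validate it against central differences to 10⁻⁶ relative
error.  It is ≤ 0 everywhere, dips at the crossover ΔHeq/ΔSeq, and
vanishes at both temperature extremes — the signature that separates an
equilibrium-induced apparent ΔCp‡ from a genuinely constant one.

**Fitting.**  Weighted nonlinear least squares on ΔG‡/T (default) or
ln k; both give identical optima on exact data because the residuals
differ by the constant factor R plus a fixed offset.  The two-state
model is linear in (ΔH3‡, ΔS3‡) once (ΔHeq, ΔSeq) are fixed, and the
heat-capacity model is linear in (ΔH0‡, ΔS0‡) given ΔCp‡.  Multistart
therefore grids the nonlinear parameters — ΔHeq ∈ {10, 20, 30, 40}
kcal/mol with ΔSeq seeded from a Keq = 1 crossing at each data
temperature, and ΔCp‡ ∈ {0 … -4} — and solves the linear pair exactly
per start before polishing with bounded least squares.  This
variable-projection initialization replaces a fixed lattice in the
linear parameters: it covers the same space with strictly better
starting residuals.  Among converged starts the best solution on the
physical branch (ΔHeq, ΔSeq ≥ 0, no large negative chemical-step
enthalpy) is returned; the sign-degenerate twin obtained by negating
ΔHeq and ΔSeq reproduces the rates exactly and is rejected with an
explicit reason.  Covariances come from s²(JᵀJ)⁻¹ via pseudo-inverse; a
condition number above 10¹⁰ flags unidentifiable parameters (e.g. ΔHeq
on exactly linear data) without failing the fit.

**Optima.**  Rate maxima are located by a 0.5 K grid bracket plus
bounded scalar minimization of -ln k; a boundary argmax reports "no
interior optimum".  The heat-capacity optimum has the closed form
T = (ΔCp‡·T0 - ΔH0‡)/(ΔCp‡ + R), used as an oracle.

## Toy EVB engine

Two diabatic surfaces V1, V2 (harmonic by default; Morse and tabulated
forms available) over one coordinate, coupled by a constant H12.  The
adiabatic ground state is Eg = (V1+V2)/2 - ½√((V1-V2)² + 4H12²), and
free energies are binned over the energy gap Δε = V1 - V2 (the diabatic
crossing sits at Δε = 0 by construction).  One dimension suffices
because the "solvent" reorganization is carried entirely by the
displacement and force constants of the diabats.

Sampling uses a seeded Metropolis random walk on the mapping potential
Vλ = (1-λ)V1 + λV2, with the proposal width auto-tuned to 30–50 %
acceptance during equilibration (defaults: 10³ equilibration and 10⁴
production steps per window; chain lengths in physical time are
meaningless for toy surfaces).  The λ ladder has 51 windows by default
and is executed outward from λ = 0.5, each window seeded with its inner
neighbour's final coordinate.  Free energies between adjacent windows
use the exponential-average estimator in the log domain; for the linear
mapping the perturbation is (λj-λi)(V2-V1), so its spread (in units of
RT) doubles as the overlap diagnostic and triggers a warning above 4 RT.

Profiles follow the standard umbrella form,

    ΔG(Δε bin) = ΔG_FEP(λ) - RT ln ⟨ δ_bin · exp(-(Eg - Vλ)/RT) ⟩_λ,

with V1 (or V2) replacing Eg for the diabatic profiles.  Because both
Eg - Vλ and the diabatic exponents are functions of the binned gap
itself, the per-bin estimates are low-variance and the dominant noise is
bin occupancy.  Bins covered by several windows take the window with the
largest count (count-weighted averaging behind a flag); bins under 25
samples are dropped — a floor of 10 admitted occasional far-tail bins
whose occupancy noise, amplified by chain autocorrelation, could
displace a well minimum.  Bin edges are aligned to multiples of the bin
width so that sampled and quadrature profiles estimate identical binned
quantities.  Wells and the barrier top are read with a local parabolic
refinement (±3 bins), which removes most of the max-of-noisy-bins
selection bias and makes the sampled barrier estimator consistent with
the deterministic one.  Reorganization energies are read as one diabat's
free energy at the other diabat's minimum position, minus its own
minimum.

For 1D systems the same binned profiles are computed exactly by
quadrature over the coordinate.  This is the closed-form oracle for the
sampler (Marcus relations: λ = ½kd², ΔG‡_diabatic = (λ+ΔG0)²/4λ) and the
default calibration engine: a fixed-point iteration moves the state-2
gas shift α one-for-one with the reaction free energy error and the
coupling H12 roughly one-for-one with the barrier error, converging in a
handful of iterations.  The toy solution-reference system uses k = 220
kcal/mol/Å² diabats displaced 1 Å (λ = 110 kcal/mol), which places the
uncoupled crossing a few kcal/mol above the 23.9 kcal/mol target so the
calibrated H12 (≈ 3 kcal/mol) has headroom; calibration reproduces
ΔG‡ = 23.9 and ΔG0 = -1.1 kcal/mol exactly, and blind re-simulation with
fresh seeds recovers them within twice the replicate s.e.m.

Temperature scans replicate the whole FEP/profile construction per
temperature (default ladder 278–313 K in 5 K steps, the standard
eight-temperature protocol) with independent spawned seeds; the s.e.m.
is estimated from the replicate barriers, and temperatures whose profile
construction fails are reported, never silently dropped.

## Gating model

The dead-end state is given a structural reading: a two-state
bound/unbound contact obeying van 't Hoff exactly, each state emitting a
Gaussian distance distribution.  The distance parameters (bound
2.8 ± 0.25 Å, unbound 4.5 ± 0.6 Å) are synthetic plumbing consistent
with an intact vs broken hydrogen bond; they are not fitted to any
measured density and no claim is made about real distance distributions.
A harmonic restraint (default 5 kcal/mol/Å², a deliberately weak value)
multiplies the density by its Boltzmann factor and renormalizes.

Under a restraint the bound fraction is defined as the reweighted
probability mass below the bound/unbound midpoint distance rather than
by mixture-component label.  The two definitions agree when the modes
are well separated, but only the distance-mass definition has the
correct strong-restraint limit: as the force constant grows all mass
concentrates at the bound distance and the gate-disabled rate curve is
recovered exactly, whereas component labels retain a Keq-proportional
residue from the unbound mode's density tail at the restraint target.

Composition with a chemical-step barrier series (interpolated linearly
in ΔG‡/T vs 1/T; extrapolation refused) gives kcat(T) = k3(T)·P_bound(T).
An unrestrained gate with the published equilibrium parameters on linear
chemical barriers produces an interior rate maximum on 278–313 K and a
broken Arrhenius plot; the restrained curve is monotone with an
Arrhenius R² above 0.98.  Because the mechanistic composition *is* the
two-state model, fitting the macroscopic model to the composed curve
returns the gate thermodynamics — the end-to-end consistency test.

## Synthetic data

Noise is Gaussian on barriers, never independently on rates: each
temperature takes n replicate draws whose spread is chosen so the
replicate mean has the target s.e.m., drawn per temperature from
0.08–0.14 kcal/mol (the spread characteristic of well-converged
replicated free-energy calculations) unless fixed.  Rate noise is the
TST image of the barrier noise, hence log-normal.  The generating truth
is always recorded next to the data.  The generator emulates the
between-replicate scatter of free-energy estimates only; it does not
emulate within-trajectory autocorrelation, force-field error, or any
protein-level structure, so passing recovery tests bound estimator
behavior under the stated noise model, not under real simulation error.

## Problem sizes and numerical choices

Tests run the toy Marcus systems (k = 40 diabats) with 21 windows and
3×10³ production steps per window, 8 replicates; the reference-system
checks use the full 51-window protocol with 8×10³ steps and 10
replicates; parameter-recovery statistics use 500 seeded datasets at
σ = 0.1 kcal/mol on 8 temperatures.  These sizes give standard errors
small enough that every oracle comparison is made at 2–3 s.e. without
being wasteful.  Degenerate inputs are errors, not silent fixes:
non-increasing temperature grids, negative s.e.m., infeasible
calibration targets (barrier below max(0, ΔG0)), λ outside [0, 1], and
profiles lacking two wells all raise with specific messages.

## Known limitations

* The EVB engine is 1D with constant coupling; it validates estimators
  and reproduces calibrated energetics, but carries no information about
  real protein electrostatics or the microscopic origin of ΔH‡/ΔS‡.
* The adiabatic profile near an uncoupled (H12 = 0) crossing has a cusp;
  binned values there depend on bin width at the 0.1 kcal/mol level, so
  cusp-region comparisons use the diabatic crossing instead.
* The dead-end model is the reversible limit; the time-dependent
  irreversible-inactivation extension is out of scope.
* Published figure point values are not reproduced — they require
  microsecond-scale protein simulations — only the printed parameters,
  closed forms, and property-level behaviors are.
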