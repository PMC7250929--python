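# coldkin

Desk-scale analysis of anomalous temperature optima in cold-adapted
enzymes: a toy empirical-valence-bond (EVB) free-energy engine, Arrhenius
decomposition of temperature-dependent activation free energies, and the
two competing kinetic models that can explain a rate maximum far below
the protein's melting temperature.

## The problem

Psychrophilic (cold-adapted) enzymes trade activation enthalpy for
activation entropy — ΔH‡ is lower and ΔS‡ more negative than in
mesophilic orthologs — which keeps them fast in the cold.  Some of them
also show a puzzling rate optimum 15–20 °C *below* their melting
temperature, so thermal inactivation cannot be global unfolding.  Two
macroscopic models reproduce such a curved Arrhenius plot:

* **Two-state dead-end model.**  The Michaelis complex ES is in
  equilibrium with an unreactive state ES′, so

  ```
  kcat = k3 / (1 + Keq),   Keq = exp(-(ΔHeq - T·ΔSeq) / RT)
  ```

  A large ΔHeq balanced by a large ΔSeq switches the population near a
  crossover temperature ΔHeq/ΔSeq and shuts the enzyme down above it.
  The apparent activation parameters interpolate between the chemical
  step (low T) and the chemical step minus the equilibrium (high T):

  ```
  ΔH‡app ≈ ΔH3‡ - Φ·ΔHeq,   Φ = Keq / (1 + Keq)
  ```

  and the implied apparent activation heat capacity,
  ΔCp‡app = -ΔHeq²·Φ(1-Φ)/(RT²), is a negative *dip* centred on the
  population transition, vanishing at both temperature extremes.

* **Activation heat-capacity model.**  A constant negative ΔCp‡ between
  transition state and ground state makes

  ```
  ΔH‡(T) = ΔH0‡ + ΔCp‡ (T - T0),   ΔS‡(T) = ΔS0‡ + ΔCp‡ ln(T/T0)
  ```

  which curves the Arrhenius plot even for a one-state mechanism, but
  predicts unbounded apparent enthalpies at temperature extremes.

Fitted to the same eight-temperature rate curve the two models are
essentially indistinguishable; they are discriminated only by their
extrapolations and by mechanistic evidence.  The package supplies that
mechanistic layer at toy scale: a two-state EVB engine (λ-mapping free
energy perturbation binned over the energy-gap coordinate Δε = V1 - V2,
with Marcus-theory closed forms as oracles) and a thermodynamic model of
the gating enzyme–substrate contact whose rupture creates the dead-end
state; a harmonic restraint on that contact abolishes the optimum.

## Worked example

```python
import numpy as np
from coldkin import (
    TwoStateParams, GeneratorSpec, generate_barrier_series,
    fit_piecewise_arrhenius, fit_model, optimum_temperature,
)

params = TwoStateParams(dH3=10.2, dS3=-0.00925, dHeq=32.0, dSeq=0.10746)
series, truth = generate_barrier_series(GeneratorSpec("two_state", params, seed=1))
pw = fit_piecewise_arrhenius(series)
fit = fit_model(series, "two_state")
```

With seed 1 this prints the synthetic eight-temperature barrier series
(standard errors drawn from the 0.08–0.14 kcal/mol range typical of
replicated free-energy calculations) and then:

```
Arrhenius breakpoint: 293 K (score 7.0)
fitted dH3 = 12.8, dHeq = 29.3 kcal/mol
rate optimum: 17.0 C
```

The broken Arrhenius plot is detected near the population crossover
(ΔHeq/ΔSeq ≈ 298 K ≈ 25 °C) and the fit recovers an equilibrium enthalpy
near the generating 32 kcal/mol.  With only eight noisy temperatures the
individual enthalpy/entropy values are imprecise — the qualitative
requirement of a strongly temperature-dependent inactivation equilibrium
is what is robust, and the parameter-recovery tests quantify exactly how
imprecise (median ΔHeq error ~10 % at the standard noise level).

A command-line interface mirrors the library
(`coldkin generate | arrhenius | fit | compare-models | simulate-evb |
simulate-gate | pipeline`); every subcommand reads and writes headered
delimited tables and YAML reports.

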