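# Methods

This note documents the model equations, the default parameters and why
they were chosen, the numerical settings, and the known limitations of the
package. Everything quantitative stated here is computed by the test suite
or the analysis drivers.

## pH-dependent solubility

Vardenafil carries two basic centres (pKa 4.24, 7.76) and one acidic
centre (pKa 8.68). Speciation follows Henderson–Hasselbalch with
sequential ionization: the cationic states are built by protonating basic
groups from the highest pKa downward, anionic states by deprotonating
acidic groups upward. The solubility model is

S(pH) = S₀ · (1 + Σ_states min(ratio_state(pH), factor_state − 1)),

where S₀ is the intrinsic (neutral-species) solubility and each charged
state's contribution is capped by its *solubility factor* (the maximal
ratio of that state's solubility to S₀). S₀ and the factors are estimated
by least squares on log₁₀S with factors bounded ≥ 1; the log-space
objective is needed because the measured profile spans a 600-fold range.

A capped-HH curve is slope-limited by the pKa set: between pH 5 and pH 7
it can fall at most ~100-fold for this pKa set, whereas the measurements
fall 548-fold. Since reproducing the measured profile is the acceptance
surface for this model, evaluation *inside* the measured pH span follows
the measurements themselves via monotone PCHIP interpolation on log₁₀S
(exact at every measured point); outside the span the fitted capped-HH
tails take over, rescaled for continuity at the boundary, and the result
is floored at S₀. The multi-group upper bound S ≤ S₀·(1 + Σ(factor − 1))
replaces the single-group "max factor" cap, which is not a valid bound
when several charged states contribute simultaneously at low pH.

Bile-salt solubilization uses the logP correlation for the micelle–water
partition coefficient, log₁₀K = 2.23 + 0.61·logP, as an enhancement
factor 1 + K·[BS]·v̄_w (v̄_w = 0.01805 L/mol). With fasted-state bile
(≈2–3 mM in the small intestine, 0 in stomach and colon) this is a
~10–14% effect for vardenafil.

The aqueous diffusion coefficient uses the standard small-molecule power
law D = 9.9×10⁻⁵·MW⁻⁰·⁴⁵³ cm²/s (0.599×10⁻⁵ at MW 488.61).

## Dissolution and precipitation

Monodisperse spherical particles (initial diameter 100 µm — an
approximation for the commercial tablet, sensitivity-tested in
`analysis/04_sensitivity.py`) dissolve by the Nernst–Brunner/Johnson
diffusion-layer law,

dM/dt = −3·D·M/(ρ·h·r)·(Cs − C),  h = min(r, 30 µm),

with cube-root kinetics (dr/dt = −D/(ρh)·(Cs − C)); the 30 µm
diffusion-layer cap is the standard default of this model family. True
density defaults to 1.2 g/mL (not reported for the product; the
sensitivity stage shows < 0.1% effect on exposure). Tablet disintegration
is treated as instantaneous — no disintegration data exist for the
product, and the in vitro profiles at pH 1/5 are complete well inside the
sampling window, so any realistic disintegration lag is absorbed into the
dissolution time scale. Supersaturated dissolved drug (C > Cs) reverts to
solid as a first-order process with the mean precipitation time
(τ = 900 s); dissolution and precipitation are mutually exclusive by the
sign of Cs − C, so the dissolution flux itself is never negative.

The in vitro simulator integrates this law in a closed stirred vessel
(mass balance dissolved + undissolved = dose at every step). It ignores
hydrodynamics beyond the solubility and volume terms: the paddle-speed
calculator (ε ∝ RPM³·D⁵/V at matched agitation strength) is a standalone
tool, reproducing ≈153 rpm for the 50 mL mini-paddle vessel when a 42 mm
mini-paddle is assumed against the 75 mm USP II paddle (the mini-paddle
diameter is not standardized; 42 mm is the assumption recorded here).
Because wetting and hydrodynamic effects are not parameterized, the
pH 7 / 50 mL condition is asserted only against its mass-balance cap
(solubility × volume = 2.5 mg → ≤ 12.5% of a 20 mg dose; the simulator
gives ~11%), not against the experimentally observed 4%.

## Gut transit and absorption

Nine compartments in series: stomach, duodenum, jejunum 1–2, ileum 1–3,
caecum, ascending colon. Segment geometry, pH, transit times and bile-salt
concentrations follow standard fasted-human compartmental-absorption
tables (total small-intestinal transit ≈ 3.2 h; caecum 4.19 h; ascending
colon 12.57 h); they are stored in an editable table in
`gut_model._DEFAULT_SEGMENTS`. Luminal fluid volumes are the anatomical
cylinder volume × percent fluid, with percent fluid reduced to 23% (small
intestine) and 0.5% (colon) to reflect realistic luminal water. Solid and
dissolved drug transit first-order at 1/T_n; per-segment dissolution uses
the local pH/bile solubility; dissolved drug in absorptive segments is
absorbed with kₐ = 2·Peff·ASF/R. Absorption scale factors (ASF) default
to 1 in all absorptive segments: effective permeability is referenced to
the smooth-cylinder area, and suppressing the colon would contradict the
predicted substantial colonic absorption after bypass. The stomach never
absorbs.

Fluid handling is deliberately simple: gastric fluid volume is
resting + dose water, relaxing first-order to resting at the gastric
transit rate; intestinal volumes are static at baseline. Dose water is
250 mL (healthy) or 50 mL (post-surgery).

Surgery rewiring: SG sets the stomach to 10 mL / pH 5.0 / 0.12 h; OAGB
additionally sets gastric pH 7.0 and bypasses duodenum + jejunum, routing
gastric outflow directly to ileum 1 with unchanged distal transit times
(no post-surgical intestinal adaptation is modeled). Bypassed segments
receive no drug and contribute zero absorption by construction.

Hepatic first-pass extraction (FPE = 0.83) applies uniformly to all
absorbed drug regardless of absorption site; site-dependent extraction is
excluded by the near-identical pre/post-bypass AUC, since the bypass
shifts absorption distally without changing total exposure.

## Systemic disposition

Linear mammillary three-compartment model with k₁₀ = CL/Vc. The reported
"Vd 0.800 L/kg" is read as the **central** volume Vc: the micro-constant
parameterization requires a central volume, and only this reading
reproduces the reported 4.43 h terminal half-life (the eigenvalue
computation in `terminal_half_life` gives 4.427 h; the test suite checks
the characteristic cubic s³ + 7.04425s² + 4.9554875s + 0.60703125 against
the same eigenvalues). Plasma, not blood, is the model currency; the
blood/plasma ratio (0.83) and fraction unbound (5%) are carried as
metadata — they would drive tissue partitioning in a full perfusion-limited
PBPK model, which is out of scope here (the lumped model matches how the
disposition parameters were estimated).

Non-compartmental metrics: C_max/T_max from the output grid; AUC(0–t) by
linear trapezoid; λz by log-linear regression over the last third of the
post-T_max points below C_max/2 (minimum three; otherwise AUC(0–∞) is
flagged missing); AUC(0–∞) = AUC(0–t) + C_last/λz. Parameter fitting uses
relative-error (1/C-weighted) least squares against the analytic
eigen-solution, with three multi-start scalings of generic distribution
constants; CL and Vc are the well-identified targets (recovered to < 1%
noise-free, median < 10% at 10% CV across 20 seeded replicates).

## Numerical settings

The coupled gut + disposition system (≈40 states) is integrated with
LSODA at rtol 1e−8 on a 0.01 h output grid over 24 h (≥ 5 terminal
half-lives, needed for T_max resolution around 0.8 h and stable AUC
extrapolation); worst-case mass-balance defect in the test scenarios is
~1e−12 relative. The particle-radius state is floored at 10⁻⁶ cm and
shrinkage is gated by a smooth M/(M + ε) factor so empty compartments keep
a finite radius. The in vitro vessel uses rtol 1e−9. A full three-scenario
study takes a few seconds on one core.

## Synthetic data

The profile generator forward-simulates the compartmental model
analytically (eigendecomposition) and applies multiplicative log-normal
noise exp(N(0, σ)), σ = CV/100, with values below the LLOQ (default
0.1 ng/mL, a conventional bioanalytical floor) censored to zero, under a
fixed seed. It emulates assay scatter on mean profiles only: no
inter-individual variability, absorption-phase model mismatch, or
correlated residuals — so fit-recovery tests demonstrate estimator
correctness, not robustness to real clinical heterogeneity. Observed and
reference-predicted PK parameter tables are shipped verbatim as fixtures.

## Design choices on open points

- **Post-SG gastric pH** defaults to 5.0 (the scenario definition), even
  though day-1 ex vivo gastric pH after surgery is ≈ 7; the physiology
  object is editable if the higher value is wanted.
- **Mini-paddle diameter** 42 mm (see above).
- **Solubility-factor values** are reported as fitted metadata; the exact
  cap algebra of the reference software is not published, so printed
  factor values are not reproduction targets — the measured profile is.
- **"Maximum liver concentration"** has no direct counterpart in a lumped
  disposition model; the peak hepatic inlet flux (total absorption flux
  presented to the liver) is used as its directional proxy, and falls
  ~53% after bypass in the packaged scenario.

## Known limitations

- The proximal-intestinal solubility of the model between the measured
  pH 5 and pH 7 points is interpolation, not measurement; the steep
  log-PCHIP descent makes ileal dissolution after bypass somewhat slower
  than a flatter (capped-HH-shaped) curve would, which damps the simulated
  post-bypass C_max relative to reference implementations that simulate
  from their fitted factor curve.
- No enterohepatic recirculation, transporters, gut-wall metabolism,
  nonlinear clearance, or population variability.
- Monodisperse particles and instantaneous disintegration; fasted state
  only; one-anastomosis bypass only (Roux-en-Y geometry differs).
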