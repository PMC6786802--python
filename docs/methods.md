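# Methods

## Model

The whole-cell inwardly rectifying current is a sum of `n` independent
constituents, one per population of identical channels (same α-subunit
assembly). For I_KAch the default is `n = 2`, matching the two functional
GIRK assemblies found in atrial cells (GIRK1/4 heterotetramers and GIRK4
homotetramers); the implementation supports general `n`, but which assembly
corresponds to which population is deliberately left abstract (populations
are labelled 1 and 2) because the assignment is not experimentally
determined.

Drug binding is assumed fast compared with the conformational changes that
alter conductivity, so binding-state probabilities take their equilibrium
values at every concentration `c`:

- **Sequential pocket** (population 1, activation): a hydrophobic pocket
  binds one or two drug molecules in sequence,
  `x0 = 1/(1 + c/K1 + c²/(K1·K2))`, `x1 = x0·c/K1`, `x2 = x0·c²/(K1·K2)`.
- **Two independent sites** (population 2, inhibition): each site binds one
  molecule, `x0 = 1/(1 + c/K3 + c/K4)`, `x1 = x0·c/K3`, `x2 = x0·c/K4`.
  `K4` may be infinite (represented as the float `inf`, parsed from the
  literal token `inf` in parameter files), in which case `x2 = 0` exactly —
  not approximately, as a large-but-finite stand-in would give.

Each state `k` carries a dimensionless conductivity factor `h_k_j`; the
voltage dependence is separated into a common rectification conductance

```
g(U) = 0.8 · [ 0.325/(1 + exp((U+80)/5)) + 3/(1 + exp((U+150)/52)) ]
```

in μS-like model units. Because every conductivity is `h·g(U)`, the
relative effect `F(c) = I(U,c)/I(U,0)` is exactly voltage independent; the
mild voltage dependence observed for nicotine on the acetylcholine-induced
component is expressed through a sparse **override** mechanism: an exact
voltage key maps to replacement h values (the packaged nicotine set lowers
`h_2_1` from 0.085 to 0.037 at −110 mV). Overrides are exact-voltage
lookups with no interpolation, because replacement values exist only at the
voltages actually analysed.

### Units and conventions

Concentrations are carried opaquely: the model only requires `c` and the
`K`s to share units (mM for the ethanol set, nM for the nicotine set; each
parameter file declares its units). Currents are in "model units"
(conductance in the μS-like units of `g(U)` times mV); all scientific
claims checked by the tests are ratio- or shape-based, so no conversion to
current densities is attempted. The reversal voltage `U_K` defaults to
−85 mV — the holding voltage of the source experiments, where currents are
near zero — and is overridable per parameter file. The
`RectificationParams.global_scale` multiplier (default 1) reproduces the
device of halving `g(U)` when matching individual-cell current–voltage
records; whether to apply it is a per-simulation choice exposed to the
caller rather than baked into any parameter set.

## Transients

Conductivities relax toward their equilibrium values after a concentration
step by first-order kinetics, `dG_j,t/dt = (G_j − G_j,t)/τ_j`. Note the
sign: relaxation is *toward* the steady state; the opposite sign would
diverge, contradicting the observed slow saturating transients (up to
~100 s). No measured time constants exist for I_KAch, so the defaults
`τ₁ = τ₂ = 10 s` are purely illustrative and must be treated as such.
Protocols are piecewise-constant in concentration (continuous ramps have no
experimental counterpart here); trajectories use the per-segment closed
form, which the tests verify against adaptive Runge–Kutta integration.
Whether the two populations should share a time constant is unknown; both
are configurable.

## Cell-to-cell dispersion

Variability between cells is modelled entirely as redistribution of
channels between the two populations: `f1 → f1 + Δf`, `f2 → f2 − Δf`. The
mean `f1 = 0.68` (so `f1/f2 = 2.125`). Dispersion bands evaluate F(c) at
`f1 ± Δf` (0.1 for the ethanol analyses, 0.07 for nicotine); correlation
curves sweep `f1` continuously over [0.05, 0.95] by default (200 points),
a range that covers all redistribution values used in the reference
simulations (−0.6 to +0.19). When control currents are negative (inward,
e.g. at −110 mV), correlation outputs carry |I_contr| so that "larger
current" reads left to right. Note one subtlety verified analytically in
the tests: the ordering of the ±Δf band at saturating concentration is not
set by the numerator contrast alone — the drug-free baseline also shifts
with `f1`, and for the constitutive/ethanol parameter set the baseline term
dominates, putting the `+Δf` curve above the mean.

Ordinary least-squares regression of per-cell (|I_contr|, F) data uses the
standard t test on the Pearson correlation with n−2 degrees of freedom;
the p-value is undefined (NaN) below n = 3.

## Synthetic data

The generator emulates the statistical structure the dispersion model
assumes: per cell, `Δf` is drawn from a truncated normal (mean 0, sd
configurable, truncated so `f1 + Δf ∈ [0, 1]`, which automatically keeps
`f2 − Δf` valid), and control/drugged currents optionally receive
independent multiplicative log-normal noise — patch-clamp magnitudes vary
on a relative scale and the ratio F must stay positive. Defaults: 10 cells
per concentration, Δf sd 0.05, noise sd 0.05. Reference concentration
grids: 0.8, 8, 20, 80 mM for ethanol and 4, 40, 400 nM for nicotine (the
nicotine grid is the experimentally printed one; the ethanol grid is this
package's choice of a representative four-point log-spaced design around
the emphasised 20 mM concentration).

What the generator does *not* emulate: correlated drift within recordings,
series-resistance and leak-subtraction artefacts, acetylcholine
desensitisation, or any measurement-error structure beyond i.i.d.
multiplicative noise. Passing round-trip tests therefore demonstrate the
estimator's correctness under the model's own assumptions, not robustness
to real-world recording artefacts. How much of the observed scatter is
measurement error versus genuine Δf variation is unknown; both knobs are
exposed and neither is fitted by default.

## Fitting

Calibration is bounded nonlinear least squares on the relative-effect
curve: minimise `Σ wᵢ (F_model(cᵢ) − Fᵢ)²` with `wᵢ = 1/SEᵢ²` when
standard errors are available (concentration–response data are typically
reported as mean ± SE). Dissociation constants are optimised on a log10
scale. The objective is multimodal in (K, h) space, so the fitter runs a
multistart (default 16 starts: the initial model's values plus seeded
log-/uniform draws over the bounds) and reports the dispersion of
estimates across starts.

Identifiability:

- `K1 = K2` is enforced by default (the reference parameter sets list a
  single value); an option relaxes it.
- F-only data are invariant to a common rescaling of all h factors (F is a
  ratio), so a fit that frees every h is rejected; keep at least one h
  fixed (h_0_1 by convention) unless absolute currents are supplied.
- A flat objective across the start points — e.g. any parameter that only
  multiplies an occupancy that is identically zero, such as `h_2_2` when
  `K4 = ∞`, or any `K` of an equal-h population — is flagged
  `non_identifiable`; the best candidate is still returned.
- `profile_parameter` re-fits the remaining free parameters along a grid of
  one parameter; convex profiles with an interior minimum indicate
  practical identifiability, flat profiles structural redundancy.

No goodness-of-fit metric is inherited from the reference calibration
(which was manual); the least-squares objective is this package's choice.
Time constants are never fitted (no transient data exist).

## Problem sizes and numerical choices

Occupancy closed forms are validated against a numerical solve of the
linear balance equations (1000 random draws, agreement < 1e−10). Transient
closed forms are validated against RK45 integration at rtol 1e−10
(agreement < 1e−8 over 100 s). The parameter-recovery study uses 50
replicate ensembles of 10 cells at the four-point ethanol grid with Δf sd
0.05 and a 3-parameter fit (K₁=K₂, h₁₁, h₂₁ — the parameters that
influence the constitutive component's curve; the inhibition-site constants
are structurally dead there because population 2 has equal h factors);
median worst-parameter relative error is typically below 10%. Multistart
counts are 16 for single fits and 6 within the replicate study. Occupancy
triples are validated to sum to 1 within 1e−9 at construction; voltages
equal to `U_K` give exactly zero current by construction.

## Known limitations

- Equilibrium binding only; no occupancy-resolved kinetics (binding is
  assumed much faster than the conformational response).
- The mechanism of rectification is not modelled; `g(U)` is a formal
  empirical expression, and intracellular modulators (PIP₂, Na⁺, Mg²⁺,
  polyamines) enter only implicitly through the h values.
- The assignment of activation to population 1 and inhibition to
  population 2 is a simplification; real populations likely host both
  mechanisms with one dominating.
- No Nernst computation of `U_K` from ion concentrations (out of scope by
  design; the value is a config constant).
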