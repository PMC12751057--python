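# Methods

## The kinetic model

The mechanism is the minimal double-displacement sequence for a nucleotide
*N*-hydrolase operating through a covalent enzyme intermediate:

```
E + S ⇌ ES        k1 (μM⁻¹s⁻¹) / k2 (s⁻¹)
ES    → E–X + P   k3 (s⁻¹)
E–X   → E + Q     k5 (s⁻¹)
```

k3 and k5 are macroscopic constants, each lumping a chemical step with the
release of one product.  Both are treated as irreversible: under initial-rate
and pre-steady-state conditions product concentrations are far below any
rebinding regime, and the hydrolytic second step is strongly exergonic.  The
anionic nucleobase formed transiently on bond cleavage is assumed to be
protonated too fast to accumulate, so it never appears as a species.  Three
nested variants are exposed: `binding_only` (for binding kinetics with
catalytically dead enzyme), `two_step` (single-turnover experiments, enzyme
in excess, signal from the first half-reaction only) and `three_step` (the
full cycle, needed for multiple-turnover burst data).

Half-of-the-sites reactivity is handled by an `active_fraction` on the
enzyme: only that fraction of the total enzyme enters the conservation law.
The default is 1; 0.5 reproduces the situation where only one subunit of a
homodimer turns over at a time.

Closed-form steady-state consequences of the scheme:

- specificity constant k_cat/K_M = k1·k3/(k2 + k3) (flux through the first
  half-reaction; reported in M⁻¹s⁻¹),
- turnover number k_cat = k3·k5/(k3 + k5) (series combination of the two
  half-reactions),
- K_M = (k2 + k3)·k5 / (k1·(k3 + k5)).  The K_M expression is not a textbook
  constant for this scheme; it was derived from the quasi-steady state of the
  three-step cycle and cross-checked against the ODE solution before use
  (see `test_quasi_steady_state_rate_matches_closed_form`),
- apparent dissociation constant K_D^app = k2/k1 (μM).

## Numerical integration

Units are fixed internally at μM and s.  The ODE is integrated with LSODA
(stiff-capable, switching) at rtol 1e-8 and atol 1e-13 μM, in *reduced
coordinates*: only the complexes/products not fixed by conservation (ES; ES,
E–X; or ES, E–X, Q) are state variables, and E, S, P are reconstructed from
the conservation sums.  Conservation therefore holds to machine precision in
every output, and integrator failure cannot masquerade as a conservation
leak.  The tight atol keeps undershoot below zero under the 1e-12 μM
tolerance enforced on output; concentrations are never clipped — a larger
undershoot raises `IntegrationError`.  Rate constants of exactly zero are
admitted (the no-flux limit); ratios and Eyring conversions demand strictly
positive values.

A caution on the pseudo-first-order limit: the exact relaxation rate of the
one-step binding ODE is k1·√((E₀+S₀+K_D)² − 4E₀S₀) ≈ k1·(E₀ − S₀) + k2, so
the textbook k_obs = k1·E₀ + k2 carries a relative error of order S₀/E₀.
The 0.5% agreement asserted in the tests is checked at ≥100-fold enzyme
excess, where it genuinely holds; at 10-fold excess the deviation is ~10%.

## Observables

Absorbance is a linear Beer–Lambert projection of species concentrations.
The nucleobase chromophore resides in S, ES and P; the covalent intermediate
and the sugar phosphate are dark.  Signs of the binding (ES − S) and
cleavage (P − S) response differences at the four canonical wavelengths:

| λ (nm) | binding | cleavage |
|--------|---------|----------|
| 251    | −       | +        |
| 264    | −       | −        |
| 275    | 0       | −        |
| 286    | +       | −        |

Default magnitudes are synthetic-scale choices: ±0.0018 AU/μM for the
binding/cleavage deltas and 0.0051 AU/μM for the substrate baseline, at the
0.5 cm reference path (of order Δε ≈ 3.5×10³ and ε ≈ 10⁴ M⁻¹cm⁻¹).  They set
the signal-to-noise of synthetic traces, never the kinetics; per-species
complex coefficients are not tabulated anywhere, so no attempt is made to
reproduce real differential spectra quantitatively.

## Synthetic data

The generator emulates a stopped-flow absorbance instrument: logarithmic
(default start max(dead time, 10⁻⁴ s)), split-time or uniform sampling; a
0.9 ms dead time during which the reaction already proceeds (integration
always starts at mixing, t = 0); additive i.i.d. Gaussian noise with
default sd 0.002 AU, the scale typical after averaging a few pushes.
Initial-rate datasets carry multiplicative noise at a default 5% CV, since
initial-rate errors scale with signal.  All randomness flows through a
single integer seed; identical seeds give bit-identical data.

What the generator does *not* emulate: mixing artefacts, photobleaching,
baseline drift, correlated noise, lamp flicker.  Passing recovery tests on
these data therefore demonstrates correctness of the estimation machinery
under the stated noise model, not robustness to real instrument pathology.

## Analytic fits

`fit_equation` wraps lmfit with data-driven starting values (saturation
models from the max-rate/half-max interpolation; the burst model from the
terminal slope, its back-extrapolated intercept and a log-linear fit of the
early residual; lines by least squares), so fits are reproducible without
user guesses.  Replicates are always fitted pooled, never averaged.
Standard errors come from the curvature of the SSR surface at the optimum;
singular curvature yields NaN errors rather than invented ones.

The burst model A(t) = A₀·e^(−k_burst·t) + v·t is fitted with an extra
constant baseline, because projected traces carry the time-invariant
chromophore contribution of unreacted substrate; instrument software usually
zeroes this before fitting.  Two caveats established while validating the
closed-form burst oracle P(t) = E·(k3/λ)²·(1 − e^(−λt)) + E·(k3k5/λ)·t,
λ = k3 + k5 (valid at saturating substrate, derived from the reduced cycle
and verified against the ODE): at sub-saturating substrate the apparent
burst rate is scaled by the fractional saturation S/(S + K_D), and the
amplitude approaches the active-enzyme concentration only when k3 ≫ k5.

Burst-vs-line discrimination is an explicit rule replacing by-eye judgement:
the exponential term must pass an F-test at α = 0.05 *and* its amplitude
must exceed 3× the trace noise sd.

One identifiability note: for the competitive-inhibition rate law a single
saturation curve at one inhibitor concentration determines only k_cat and
the apparent K_M(1 + I/K_i), so the uninhibited K_M is a fixed input and
K_i is extracted from the apparent shift.  Similarly, the quadratic
tight-binding law converges to the hyperbolic one within 0.1% at
E_T = K_M/100 only for S ≳ 3·K_M; the deviation at low S is of order
E_T·K_M/(S·(S + K_M)).

## Global fitting and confidence contours

`global_fit` minimises the total SSR over all traces.  Rate constants (and
optional per-wavelength amplitude scales) are optimised in log₁₀ space —
this enforces positivity and conditions a parameter set spanning more than
five orders of magnitude (k1·S ~ 10² s⁻¹ against k5 ~ 10⁻³ s⁻¹) — by
trust-region least squares with finite-difference Jacobians and five seeded
multistarts perturbed log-uniformly (±0.5 decades) around the initial
values.  Per-trace additive baselines are profiled analytically (stopped-flow
baselines differ between pushes); traces are weighted 1/σ per point when
noise levels differ, uniformly otherwise.  Standard errors are mapped back
to natural units by the chain rule.  Flat directions are flagged two ways:
near-null singular values of the Jacobian (with an absolute floor tied to
the residual scale, since a truly zero Jacobian appears as finite-difference
noise) and relative standard errors above 1000%.  A binding-only problem
observed only at 275 nm — where binding produces no signal — flags both rate
constants rather than reporting them.

Confidence regions use the SSR-ratio construction: a parameter pair is
pinned on a grid, every remaining free parameter is re-optimised at each
node, and the region is bounded where SSR/SSR_min exceeds
1 + (2/(n−p))·F₀.₉₅(2, n−p).  The F-quantile form was chosen over a fixed
ratio because it adapts to the number of points and parameters; nodes where
re-optimisation fails are marked invalid, never interpolated.  On a linear
model the construction reproduces the analytic confidence ellipse exactly
(tested), and its empirical coverage of the generating parameters over
seeded noisy replicates is ≈95% (tested at ≥85% over 50 replicates).  The
reported best fit is parameterisation-invariant: fitting (k1, k2) or
(k1, K_D) reaches the same SSR minimum.

## Energy landscapes and thermodynamics

Eyring conversion at κ = 1, R = 1.98720425×10⁻³ kcal mol⁻¹K⁻¹,
k_B/h = 2.08366×10¹⁰ K⁻¹s⁻¹, default T = 298.15 K (all experiments at
25 °C).  The landscape orders E+S, ES, TS1, E–X+P, TS2, E+P+Q with E+S at
zero.  The ES well depth is RT·ln(K_D/C_ref) with a configurable reference
concentration (default 10 μM, the substrate concentration of the
single-turnover experiments) — a bimolecular step has no intrinsic
unimolecular free energy, and this choice shifts only the E+S state, never
the barriers.  The wells after each irreversible step are not fixed by rate
data at all; they are drawn a configurable 2 kcal/mol below the preceding
well purely for presentation.  Applying the inverse Eyring relation to every
barrier reproduces the input rate constants exactly.

Binding thermodynamics close the triple ΔG = RT·ln K_D (1 M standard
state) and TΔS = ΔH − ΔG identically.  Note that with ΔH = −21 and
ΔG = −7.9 kcal/mol the identity gives TΔS = −13.1 kcal/mol; a value of
−13.3 arises only from an unrounded ΔH.

## Brønsted analysis and calibrations

The Brønsted fit is weighted least squares of log₁₀(k_cat/K_M) on
leaving-group pK_a, with fitting errors propagated to the log scale as
σ/(value·ln 10) when supplied and uniform weights otherwise.  Base-10
logarithms throughout: the interpretation of β_LG ≈ −1 as near-complete
negative-charge development presumes the decadic convention.  The slope is
exactly invariant under rescaling all k_cat/K_M (the intercept absorbs it)
and under shifting all pK_a (the intercept moves by β_LG per unit).

pK_a titrations fit A(pH) = A_acid + (A_base − A_acid)/(1 + 10^(pK_a − pH));
fits are flagged non-converged when the amplitude is indistinguishable from
the residual scatter (no transition) or the pK_a falls outside the sampled
range.  Extinction standard curves are fitted with a free intercept —
baseline offsets are common and forcing the line through zero hides them —
and ε is taken from the slope alone.

## Problem sizes used by the acceptance script

The desk quantities (barriers, transit time, specificity limit, binding
ΔG) are closed-form evaluations of printed inputs.  The burst-amplitude
check simulates the three-step cycle at 10 μM enzyme / 50 μM substrate on a
2000-point logarithmic grid to 60 s and fits the burst equation to the
275 nm projection.  The recovery check generates four 286 nm single-turnover
traces (enzyme 11/22/44/88 μM over 10 μM substrate, 1000 points each to
15 s, 0.002 AU noise, seeded) and refits k1, k2, k3 globally with three
multistarts; across seeds the recovered k3 sits within ~3% of the generating
value.

## Known limitations

- Reversible chemistry (k4, k6) and product rebinding are out of scope; so
  is any pH-rate modelling.
- Response-coefficient *shapes* are synthetic; only their signs and rough
  magnitudes are anchored to measured differential spectra.
- The FitSpace threshold convention is the F-quantile form; other software
  uses fixed chi-square thresholds, so boundary positions can differ
  slightly between implementations even on identical data.
- Standard errors are local (curvature-based); for strongly correlated
  pairs the SSR-ratio contours, not the marginal errors, are the honest
  uncertainty statement.
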