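# dnphkin

Pre-steady-state kinetic modelling of double-displacement nucleotide
*N*-hydrolase catalysis (DNPH1-type enzymes), built for mechanistic enzyme
kineticists who work with multi-wavelength stopped-flow absorbance data.

DNPH1 hydrolyses the *N*-ribosidic bond of 5-hydroxymethyl-2'-deoxyuridine
5'-monophosphate in two half-reactions through a covalent deoxyribosylated
enzyme intermediate.  The minimal mechanism is

```
E + S  ⇌  ES          k1 (μM⁻¹s⁻¹), k2 (s⁻¹)
ES     →  E–X + P     k3 (s⁻¹)   chemistry + nucleobase release
E–X    →  E  + Q      k5 (s⁻¹)   intermediate hydrolysis + sugar-phosphate release
```

with the two chemical steps macroscopic and irreversible.  The package
implements, end to end:

- **Mass-action simulation** of the binding-only, two-step and three-step
  variants (stiff-capable implicit integration in reduced coordinates, so
  enzyme and substrate conservation hold to machine precision).
- **Observable projection**: Beer–Lambert mapping of species concentrations
  to absorbance at the four diagnostic wavelengths (251/264/275/286 nm),
  where binding and cleavage carry distinct sign patterns — 275 nm is blind
  to binding and reports chemistry alone.
- **Synthetic data generation** emulating the instrument: logarithmic,
  split-time or uniform sampling, 0.9 ms dead time, 0.5 cm path, seeded
  Gaussian noise; plus initial-rate datasets for all analytic models.
- **Analytic-equation fits** (`fit_equation`): Michaelis–Menten, the
  quadratic tight-binding rate law, competitive inhibition, Hill IC₅₀,
  the linear specificity regime, the exponential-burst-plus-line equation
  `A(t) = A₀e^(−k_burst·t) + v·t`, Brønsted lines, pKa sigmoids and
  extinction standard curves — with an F-test burst-vs-line discrimination
  rule (`model_discrimination`).
- **Global ODE fitting** (`global_fit`): trust-region least squares over
  multiple traces and wavelengths with seeded multistarts, profiled
  per-trace baselines, derived K_D^app = k2/k1, and flat-direction
  (unidentifiability) flagging.
- **Confidence contours** (`fitspace_contour`): SSR-ratio surfaces over a
  rate-constant pair with all other parameters re-optimised at every grid
  node and an F-quantile boundary — the standard way to see, e.g., that
  equilibrium-dominated binding data constrain only the ratio k2/k1.
- **Energy landscapes** (`build_landscape`, `dG_from_rate`): Eyring
  transition-state-theory conversion ΔG‡ = RT·ln(κ·k_B·T/(h·k)) at κ = 1,
  reaction-coordinate profiles, and equilibrium binding thermodynamics
  (ΔG = RT·ln K_D, TΔS = ΔH − ΔG).
- **Brønsted analysis** (`bronsted_fit`): weighted fit of
  log₁₀(k_cat/K_M) = β_LG·pK_a + log C over a leaving-group series.

## Worked example

Generate a synthetic single-turnover experiment (286 nm, 10 μM substrate,
enzyme in excess at 11–88 μM) and refit it globally with the two-step model:

```python
from dnphkin import *

scheme = build_scheme("two_step")
true = RateConstantSet(k1=1.0, k2=2.36, k3=0.219)
conds = [ReactionConditions(enzyme_total=e, substrate_total=10.0)
         for e in (11, 22, 44, 88)]
sampling = SamplingSpec(mode="logarithmic", n_points=1000, t_end=15.0)
traces = generate_stopped_flow_set(scheme, true, conds, [286], sampling,
                                   noise_sigma=0.002, seed=1)

problem = GlobalFitProblem(scheme=scheme, traces=tuple(traces),
                           free=("k1", "k2", "k3"),
                           init=RateConstantSet(k1=0.5, k2=1.0, k3=0.5))
fit = global_fit(problem, seed=1, n_starts=3)
```

which prints (via the estimates and standard errors on `fit`):

```
k1 = 1.023 +/- 0.018      # μM⁻¹ s⁻¹, bimolecular association
k2 = 2.526 +/- 0.072      # s⁻¹, dissociation
k3 = 0.217 +/- 0.002      # s⁻¹, N-ribosidic bond cleavage
KD_app = 2.47 uM          # k2/k1
kcat/KM = 8.1e+04 M⁻¹ s⁻¹ # k1·k3/(k2+k3), first-half-reaction flux
dG(k3) = 18.36 kcal/mol   # Eyring barrier out of ES at 298.15 K
```

The generating values (k1 = 1, k2 = 2.36, k3 = 0.219) are recovered within
the noise; k3 is the rate-determining cleavage step, and its Eyring barrier
of ~18.4 kcal/mol is the activation free energy of the first half-reaction.

The same pipeline is scriptable from the shell:

```sh
dnphkin simulate --variant two_step --k1 1 --k2 2.36 --k3 0.219 \
    --enzyme 11 --enzyme 88 --substrate 10 --wavelength 286 \
    --seed 1 --out-dir traces/
dnphkin global-fit --config fit.yaml --seed 1 --out-dir fit/
dnphkin fitspace --config fit.yaml --pair k1 k2 --grid 0.3:3:11 0.8:8:11 \
    --seed 1 --out-dir contour/
dnphkin landscape --k1 1 --k2 2.36 --k3 0.219
dnphkin bronsted --data bronsted.csv
```

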