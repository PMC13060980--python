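# Methods

## Model and dosing

The model is a four-state ODE system for cancer (C), CD8⁺ T cells (T)
and MDSCs (M) in volume units (mm³) and gemcitabine (G) in
concentration units (µM); see the README for the equations. All three
Gem kill terms share one Michaelis constant Km because the same
transporter (ENT1) mediates uptake in each cell type.

Doses are modeled as impulses — instantaneous jumps of the targeted
compartment (G += 3.8×10⁴ µM at day 10, T += 1.0695 mm³ at day 14) with
the integration restarted at each event — reflecting intravesical bolus
injections. The OT-1 cell-count-to-volume conversion behind the
1.0695 mm³ figure is taken as given. Between events G decays as a pure
exponential, which the test suite checks against the closed form.

**Homeostatic influx.** hT and hM are defined by requiring that
(C, T, M) = (0, T0, M0) be an exact equilibrium of the treatment-free
system:

    hT = (sMT·M0 + dT)·T0,    hM = (sTM·T0 + dM)·M0.

Because the suppression terms are bilinear (sMT·M·T, sTM·T·M), the
influxes must carry the product of suppressor and target at the
homeostatic point; any other reading leaves the "tumor-free" state
drifting, contradicting the purpose of the terms. The equilibrium is
exact in floating point (the implementation groups the terms so the
cancellation is bitwise), and a property test asserts it for random
parameterizations.

**Gem decay.** The decay time of 3 days is read as a half-life:
dG = ln 2 / 3 ≈ 0.231 day⁻¹. A mean-lifetime reading (1/3 day⁻¹) is a
defensible alternative; the value sits in the shipped config
(`best_fit.yaml`) and can be overridden.

**Integration.** The reference integrator is `scipy`'s LSODA at
rtol 1e−8 / atol 1e−10, piecewise between dose events; grid points at
an event report the post-dose state. States are clipped at zero when
within round-off (−1e−6) below it. Large ensembles (cohort screening,
eFAST) use a vectorized fixed-step RK4 (`simulate_batch`, default
h = 0.005 day, 0.002 day for the wide-range sensitivity run); its
agreement with the adaptive solver is a test (relative error ≤ 2×10⁻³
at the ultrasound days, ample against measurement noise and band
widths).

## Shipped parameter set

The study's fitted values and sampling ranges live in its supplementary
table, which is not part of the available text, so the package ships
its own synthetic-truth set, chosen once to be a self-consistent
parameterization anchored to the published quantities: the day-6
initial condition (26.85, 0.07217, 0.7288) mm³, the day-6 ultrasound
mean 27.6554 and SD 11.2253 mm³, the rCM sampling range [0, 0.5] (with
the in-vitro range 0.088–0.176 day⁻¹ interior to it), the dosing
calendar, and the qualitative treatment ordering (control > OT-1 >
Gem > Gem+OT-1 at day 20, with MDSCs a few percent of tumor volume and
T cells well under 1%). MDSC turnover is fast (dM = 2 day⁻¹) so the
MDSC fraction tracks rCM/dM; T-cell expansion (nCT = 0.003 mm⁻³day⁻¹)
keeps T below 1% of the tumor until late growth. All synthetic data,
profiles and sensitivity runs derive from this one set.

## Structural identifiability

The differential-algebra route is implemented exactly as far as the
model requires: relations are cleared of denominators, normalized monic
in their leading derivative monomial, and the coefficients of the state
monomials are read off as the identifiable combinations. Parameters are
then solved from the combinations by a greedy triangular pass (solve
any equation with one remaining unknown, substitute, repeat) with a
joint `sympy.solve` fallback; global identifiability means every
parameter has a unique solution. Full differential elimination
(characteristic sets) is out of scope — the shipped model never needs
it — and observables that would require it raise, except that removing
a state from the observed set reports non-identifiability (the
relations containing it cannot be read), which is the scientifically
correct verdict for the leave-one-out checks.

For the treatment-free model observed through total volume the
aggregated equation d(C+T+M)/dt is used with access to the individual
states when reading coefficients, mirroring the proof strategy rather
than attempting a true elimination to a C+T+M-only relation. This
yields exactly {pC/Cmax, kTC−nCT, sMT+sTM, rCM+pC, dT, dM, hT+hM}: 7
combinations against 11 parameters. For the full model observed through
C, T, M, G, the 16 parameters (hT, hM counted as the lumped influxes)
are all recovered; Km appears only in products (recovered as
(pC·Km)/pC) and hT only offset by the known OT-1 dose.

## Data handling: composition interpolation

Tumor composition over time is a piecewise-linear interpolant per arm:
100% cancer at implantation (day 0); the untreated histology line
defines all arms until treatment start (day 10); at day 14 the
flow-cytometry Gem/untreated ratio rescales the Gem-treated arms'
fractions; days 17 and 23 use arm-specific histology. Ultrasound totals
times these fractions give per-cell-type volumes. T/M volumes enter the
fit only at days 16 and 20 (nearest the histology collections); cancer
volumes at every ultrasound day.

The synthetic generator computes its histology knots and flow ratios
from the truth simulation, so the interpolation-split volumes are a
*biased* approximation of the simulated ones — exactly as in the real
procedure, where the linear interpolation cannot follow the convex
growth of the small T-cell fraction. The round-trip property test
therefore holds C to 5% but T/M only to a factor of three; the
parameter-recovery experiments use `exact_subpopulation_data` (model
volumes at the mask days), the idealized noiseless case in which the
generating truth is the global optimum.

## Synthetic-data generator

Defaults emulate the murine study design: 4 arms × 13 mice, ultrasound
days {6, 9, 13, 16, 20}, day-6 volumes from Normal(27.6554, 11.2253²)
truncated at zero (resampled, not clipped — volumes are strictly
positive), per-mouse biology through the generating triple
(nCT, rCM, kGM) drawn uniformly over the sampling ranges, and 10%
multiplicative lognormal measurement noise (mean-one convention) on
ultrasound totals. Optional per-mouse dropout censors trailing days to
exercise the digital-twin truncation rule. The generator does not
emulate histology image quantification or flow gating — knots and
ratios come from the simulated fractions — so passing tests certify the
pipeline's statistical machinery, not those measurement processes.

## Estimation

The objective is the summed relative error Σ|data − sim|/data over the
fitted points. The inner optimizer is `scipy.optimize.least_squares`
(trust-region reflective, numerical Jacobian, box bounds) on the
relative residuals: its zero-residual minimizer coincides with the
relative-error minimum, and the smooth L2 form is far better behaved
than the L1 sum; the reported objective remains the L1 summed relative
error. Stage 1 starts from the best of an n_lhs = 500 Latin-hypercube
scan (tests and analysis use 100) and polishes the top three starts.
The day-6 initial condition is fixed at (26.85, 0.07217, 0.7288, 0);
{dT, rCM, dM, dG, Km} stay fixed throughout. On noiseless data the fit
recovers every parameter to well under 1% — the 5% recovery check
passes with a wide margin.

## Practical identifiability

Profiles are computed against mean total-volume series (all four arms
jointly by default in the analysis; the machinery accepts any subset)
under plain least squares — deliberately distinct from the estimation
objective, following the respective procedures literally. The profile
objective is half the sum of squared residuals (the Gaussian negative
log-likelihood), under which the LSE* + χ²(α, n)/2 threshold gives
exact 95% coverage: on the linear-Gaussian toy the profile interval
reproduces the closed-form Wald interval, which is a test. n equals the
profiled subset size (3 for the candidate triples). The default grid is
41 log-spaced points on [0.2×, 5×] the best fit (scaled down in tests);
a parameter is identifiable when its profile has an interior minimum
and both threshold crossings are finite.

## eFAST

Implemented from the standard published scheme: search curves
x_j(s) = ½ + (1/π)·arcsin(sin(ω_j s + φ_j)) sampled at NS symmetric
points, one curve block per parameter of interest with ω_max =
⌊(NS−1)/(2M)⌋ and the complementary set spread evenly over
[1, ω_max/(2M)] (M = 4 interference factor), Nr random-phase
resamplings averaged, and a dummy parameter as the significance floor.
Si is the spectral power at ω_max and its first M harmonics over the
total power; STi = 1 − D(−i)/D with D(−i) the power below ω_max/2. The
design sizes NS = 1977, Nr = 2 match the study's 11-parameter setting.
Accuracy is validated against the Ishigami analytic indices (|ΔSi| <
0.05 at the design size; < 0.03 across ten phase seeds) and an additive
linear model. Subset ranking applies explicit weakest-link dominance
rules on the cancer-cell indices at day 20 (a subset is dropped when
its least sensitive distinguishing parameter sits below the least
sensitive distinguishing parameter of some alternative in both Si and
STi — a subset is only as informative as its weakest member), then
orders by mean STi; ties are logged, never broken silently.

## Virtual cohort and validation

Accept-or-reject screens candidates against mean ± k·SD (k = 2, edges
inclusive) of total volume at every ultrasound day of the control, Gem
and OT-1 arms; Gem+OT-1 is held out for cross-validation and simulated
only for accepted mice. Analysis runs use 25,000 candidates — the same
machinery as a 500,000 run, scaled to the package's demonstration
setting; acceptance rates on disjoint batches agree within binomial
error, which is a test. Because the synthetic arms' SDs reflect
full-range triple variability, the acceptance rate (~60%) is far higher
than with tight experimental bands; the rate is a property of the
generator's conditions, not of the screening machinery.

Validation uses the two-sample KS test per (regimen, day) at α = 0.05,
asymptotic p-values by default (arms of ~13 mice; an exact mode exists
and is checked against brute-force enumeration for n, m ≤ 8). No
multiple-testing correction is applied across days, mirroring raw
per-day reporting. Digital twins minimize the SSE of total volume over
a mouse's observed days, starting at day 9 and truncating at its last
observation; ties break to the lowest virtual-mouse id.

## Numerical and degenerate-input conventions

Zero data values among fitted points, empty KS samples, means-only
datasets for KS, holdout arms that participated in generation, and
non-covering time grids all raise explicit errors. Constant eFAST
outputs (variance at round-off level) are flagged degenerate with NaN
indices rather than divided through. Synthetic datasets, cohorts,
designs and fits are deterministic functions of their seeds.

## Known limitations

- The shipped parameter set is a calibrated synthetic truth, not the
  study's fitted values; all quantitative outputs (acceptance rates,
  profile widths, sensitivity orderings) are properties of this
  parameterization and the generator's settings.
- The eFAST sensitivity run varies parameters over [0.5×, 2×] the
  calibrated values; literature-derived ranges would widen or reorder
  the indices.
- Structural identifiability covers coefficient reading only; models
  needing genuine differential elimination are out of scope.
- The cohort is unweighted: accepted mice enter with equal prevalence.
- Single-compartment exponential Gem pharmacokinetics; no spatial or
  agent-based tumor structure.
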