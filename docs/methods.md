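# Methods

## Model class

The package evaluates multistate disease models in which an individual
occupies one of N discrete states and the instantaneous rate of the
transition `i -> j` is a cause-specific hazard `λ_ij(t, τ)` depending on model
time `t` (age, calendar trends) and sojourn time `τ` (time since entering the
current state). With both dependencies the state process is a
time-inhomogeneous semi-Markov process; its jump chain is Markov while
holding times follow arbitrary parametric distributions (constant hazard =
exponential, `b·k·τ^{k−1}` = Weibull, `p·e^{rτ}` = Gompertz, plus polynomial,
piecewise and life-table forms, all composable with proportional
hazard-ratio multipliers, lead-time adjustments, and occupancy-coupled
factors).

Rather than sampling patients, the solver transports the joint density
`f_i(t, τ)` of (state, sojourn). Along characteristics `t − τ = const` the
transport equation reduces to an ODE whose solution is exponential decay by
the accumulated total hazard; mass removed by transitions re-enters the
destination state on the boundary `τ = 0`. Occupancy `g_i(t)` is the
τ-marginal. Two extensions beyond the plain semi-Markov class are supported:

* **Sojourn-preserving transitions** `μ_ij` (e.g. entering a surveillance
  programme) move density between states at equal τ, leaving the disease
  clock untouched.
* **Occupancy-coupled hazards** `λ(t, τ, g(t))` (e.g. an SIR force of
  infection `β·g_I(t)`) make the system nonlinear; they are evaluated
  explicitly with the occupancy of the previous time step.

## Numerical scheme

Both clocks share one step `Δt`; the lattice value `F_i^{m,n}` approximates
`f_i(mΔt, nΔt)`. Each step:

1. **Characteristic advance.** `F_i^{m,n} = F_i^{m−1,n−1} · exp(−Σ_j ∫_0^{Δt}
   λ_ij((m−1)Δt+s, (n−1)Δt+s) ds)`. The segment integral is evaluated in
   closed form for every parametric family that admits one (this includes the
   singular Weibull `k < 1`, whose cumulative `b·τ^k` is finite although the
   rate diverges at τ = 0 — the solver never evaluates the pointwise rate at
   τ = 0); families without a closed form use the one-point midpoint rule.
   Piecewise families split the integral exactly at their breakpoints, making
   cumulative hazards bit-reproducible. Hazards that depend only on τ have
   their per-cell integrals precomputed once; hazards depending only on `t`
   contribute a single scalar per step, in which case the whole state decays
   by one scalar factor and no per-cell arrays are formed.
2. **Sojourn-preserving exchange.** Per τ-column, the μ-block rate matrix is
   exponentiated over the step (one matrix exponential when μ is constant),
   which conserves column mass exactly.
3. **Boundary.** Two discretisations:
   * *first-order*: rectangle rule `F_i^{m,0} = Σ_{j,k>0} Δt·λ_ji(mΔt, kΔt)·
     F_j^{m,k}` — simple but drifts in total mass at O(Δt);
   * *mass-conserving* (default): the mass each cell lost in step 1 is
     redistributed to entry boundaries in proportion to midpoint hazard
     shares `λ_ij((m−½)Δt,(k−½)Δt) / Σ_l λ_il(...)`, with the share defined
     as zero when the total midpoint rate vanishes. Total probability is then
     conserved to machine precision (the test suite asserts a residual below
     1e−12 on randomized models; in practice it is ~1e−16).
4. **Marginalisation.** `g_i(mΔt) = Σ_k Δt·F_i^{m,k}` plus point masses.

**Dirac initial conditions** (the standard "cohort enters at τ = 0" start)
are carried as explicit point masses on their own characteristics, decayed by
the same survival factors and fed into the boundary redistribution when they
lose mass. Smearing an atom into a density cell of height 1/Δt would cost an
O(Δt) bias in every downstream quantity; keeping atoms exact makes simple
models (two-state constant, pure characteristics) exact to rounding.

**Grid truncation.** The sojourn axis is capped at `max_tau` (default:
horizon plus the largest initial sojourn, so every characteristic stays
on-grid). Density that reaches the cap accumulates in a terminal bin instead
of leaking, and the accumulated mass is reported in the run diagnostics. For
sojourn-independent hazards the dynamics are unaffected by the cap, which
allows a deliberately short sojourn axis as a performance device (used for
the SIR comparison).

**Convergence.** With closed-form segment integrals, models whose mass never
re-enters a state are solved exactly along characteristics; discretisation
error enters only through the boundary quadrature (first order in Δt). Under
the generic midpoint rule the scheme is observed to converge at second order
on the two-state Gompertz benchmark (error ratio ≈ 4 per halving of Δt); the
test suite asserts at least linear decay. Accuracy degrades when the
per-step cumulative hazard approaches 1; the solver warns when it exceeds 1.

**Occupancy coupling** uses `g(m−1)` (explicit one-step lag), so coupled
models inherit a first-order time-stepping error; at Δt = 1e−3 the SIR
benchmark agrees with an adaptive high-order ODE solution to ~5e−5 in sup
norm. Characteristic precomputation is disabled for coupled hazards, and the
survival utilities and the Monte-Carlo sampler refuse coupled models
outright rather than silently ignoring the coupling.

## Survival utilities

Overall survival along an entry characteristic is `exp(−Λ_i)` with `Λ_i` the
summed closed-form cumulative hazard; cause-specific survival censors the
competing transitions, and the product over causes equals overall survival
identically. Next-transition probabilities integrate `λ_ij·S_i` with
adaptive quadrature split at hazard breakpoints; the improper `t → ∞` limit
is truncated at a configurable horizon and the neglected tail is *reported*
as an explicit bound (`S_i(horizon)`) rather than dropped, since a numeric
artifact should expose its truncation error. These utilities share the same
segment-integral code as the transport solver, so the two routes cannot
disagree by quadrature choice.

## Outcomes

QALYs and ongoing costs are utility-weighted trapezoidal integrals of
occupancy, matching the grid's first-order accuracy; optional exponential
discounting `e^{−d·t}` is available (disabled by default). Entry
probabilities integrate the boundary flux with one rectangle per step — the
scheme's own mass accounting — so that entry into an absorbing state equals
its occupancy increment *exactly*, not merely to quadrature tolerance.
Conditional risks (e.g. "5-year risk of cancer or death given alive and
cancer-free at year t") restart the solver from the stored sojourn density at
the conditioning time, restricted to the conditioning states and
renormalised: the sojourn distribution at that time is precisely what the
framework tracks, and discarding it for fresh atoms would reintroduce the
Markov approximation this model class exists to avoid. The conditioning set
is an explicit argument rather than a baked-in choice.

## Liver-disease example

The bundled four-state model (compensated cirrhosis → {decompensated
cirrhosis, liver cancer, death}, decompensated → death; cancer and death
terminal; cohort aged 55 entering compensated cirrhosis at τ = 0) uses the
published calibrated hazards. Three published renderings required a reading
decision, all kept visible rather than silently repaired:

* **Cancer onset** is printed in two inconsistent forms — a power law
  `0.0102·τ^1.377` in the parameter table and a Gompertz
  `(p, r) = (1.197e−2, 6.654e−2)` in the example code. Both are provided as
  presets; the Gompertz form is the default because machine-readable code is
  unambiguous about operator placement.
* **Compensated-cirrhosis death** `0.0336·τ^−0.238` is read as a Weibull rate
  with `k = 0.762` (singular but integrable at τ = 0).
* **Decompensated-cirrhosis death** `0.447 − 0.150τ + 0.0237τ²` is used as
  printed, although it is internally inconsistent with the same table's own
  decompensated-death risks (it implies 31.6%/99.2% annual/ten-year risks
  against printed values of 37.8%/90.6%), suggesting a corrupted rendering.
  The package does not guess a repair. Consequences: the solved ten-year
  all-cause death risk for the compensated cohort computes to 40.6% against
  the published 39.4%, and the lower end of the PSA prediction interval for
  ten-year decompensation risk computes to 27.7% against the published
  29.5% (the upper ends agree to 0.2 points). Both residuals are inherited
  from the printed parameterisation, not from solver error — the transport
  solution matches independent quadrature of the same hazards to six digits.
* The hazard-ratio spreads are read as σ = 0.117 etc. (the trailing "2" in
  "σ2 = 0.1172" being a squared-superscript artifact), a reading confirmed
  by the close match of the upper PSA interval endpoints.

Ten-year "risk" outcomes are defined as cause-specific cumulative incidence
with competing events censored, `1 − e^{−Λ_ij}`, consistent with hazards
calibrated to published survival curves; the all-cause death outcome routes
mass through decompensation by solving the three-state model with the cancer
transition censored. Life-table other-cause mortality is available as a
separate absorbing state but excluded from these outcome definitions: the
cirrhosis death hazards were calibrated against all-cause cohort survival,
so adding the life table to the same outcome would double count. Whether a
decompensated → cancer transition exists in the published model is not
stated; it defaults to off with a build switch.

The PSA draws one lognormal hazard ratio per hazard (independently — no
correlation structure is published) and records per-sample cause-specific
risks. Because cumulative hazards scale linearly in a proportional ratio,
these outcomes follow exactly from the base cumulative hazards, so the
default PSA path evaluates them in closed form instead of re-running the
transport solver 10,000 times; outcomes that genuinely need the solved
density (conditional risks) re-solve per sample when requested. Prediction
intervals are empirical 2.5/97.5 percentiles; runs are bit-reproducible
given a seed.

Hazard calibration minimises CI-weighted squared error between model
cumulative incidence and target points with BFGS (positive parameters on the
log scale, finite-difference gradients); non-convergence is flagged on the
result object, not raised. Hazard-ratio distributions are calibrated by
mapping target risk quantiles through the monotone closed-form
`HR = −log(1 − risk)/Λ`.

## Validation oracles

* A vectorised Monte-Carlo semi-Markov sampler draws sojourns by inverse
  transform — bisection to 1e−10 on the same closed-form cumulative hazards
  the solver uses — and causes from per-cause hazard shares at the drawn
  instant. Inverse transform (rather than thinning) is exact for hazards
  without a finite majorant, e.g. Weibull `k < 1`. Randomness comes from a
  counter-based Philox generator; every per-trajectory uniform is drawn
  up-front into a (trajectory × jump) table so results are independent of
  the order trajectories are processed in. The sampler consumes the same
  `Hazard` objects as the solver — rates are never re-specified in tests.
* An adaptive high-order ODE integration of the SIR system cross-checks the
  occupancy-coupled solver path.

## Synthetic data and what the tests show

No real patient data is used anywhere. The test suite validates the solver
against closed forms (exponential, Erlang, competing-risk splits,
matrix-exponential Markov reductions), against the Monte-Carlo sampler on
randomized Weibull/Gompertz models (60 occupancy checks within 3 binomial
standard errors at N = 20,000), and against the ODE oracle for SIR. The
bundled life table is a synthetic stand-in with a Gompertz–Makeham shape
(`scripts/make_life_table.py`), swappable via config; it emulates the *shape*
of national mortality, not any country's actual rates. Passing tests
therefore demonstrate correctness of the evaluation machinery given a hazard
specification — not the epidemiological adequacy of any particular hazard
choice, which must come from fitting to real survival data.

## Problem sizes and defaults

Default grid step Δt = 0.01 years for the liver model (1,000 steps over a
10-year horizon; one solve ≈ 0.5 s), Δt = 1e−3 for the closed-form and SIR
benchmarks. PSA defaults to 10,000 samples. The MC oracle uses 20,000
trajectories, giving binomial standard errors of ~0.3 points on occupancy
probabilities. These sizes were chosen so each validation is decisively
stronger than the tolerance it checks.

## Known limitations

* One sojourn clock per individual; multi-dimensional sojourn vectors
  (tracking several independent event clocks at once) are out of scope.
* The scheme is first-order in Δt at the boundary (second-order behaviour is
  observed under midpoint integration but not guaranteed for rough hazards);
  no adaptive stepping or spectral acceleration.
* Occupancy-coupled models use an explicit one-step lag; stiff couplings
  would need smaller steps.
* Survival utilities and the MC sampler require uncoupled hazards.
* `calibrate_hazard` supports the constant/Weibull/Gompertz families;
  covariate models and nonparametric smoothing are out of scope.
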