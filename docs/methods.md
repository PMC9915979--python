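# Methods

## Model structure and assumptions

The forward model maps a constant inhaled benzene concentration to the
urinary tt-MA concentration a child would present at a single void. It is a
steady-state caricature of benzene toxicokinetics built on five assumptions:

1. exposure is by inhalation only, at a constant air level;
2. blood reaches its steady-state benzene concentration instantaneously;
3. arterial delivery to the compartments is homogeneous;
4. benzene is metabolized continuously in the liver, and the urinary
   metabolite accumulates in the bladder between voids;
5. successive micturitions are 180 minutes apart.

Four compartments are carried (richly perfused, fat, poorly perfused,
liver), each filling along the saturable curve
`C_i(t) = Q_i P_i C_art t / (V_i P_i + Q_i t)`. Only the liver feeds the
metabolism step; the other compartments matter for the `mass_balance`
arterial mode (below) and for any future extension to venous-blood
biomarkers. The curve's stated output is a concentration (mg/L): its
right-hand side is dimensionally flow·partition·concentration·time over
volume·partition + flow·time, which reduces to concentration.

The chain evaluated by `ttma_urine_forward` is:

    C_art -> C_liver(t_ss) -> C_venous = C_liver / P_liver
          -> v = Vmax C_venous / (Km + C_venous)
          -> benzene mass per void = v × 180 min
          -> tt-MA mass = f_ttma × mass × (142.11 / 78.11)
          -> tt-MA concentration = mass / void volume

with `t_ss` chosen so the liver filling curve is within 1e-6 (relative) of
its asymptote: the shortfall is `(V P)/(V P + Q t)`, giving
`t_ss ≈ V P / (Q × 1e-6)`. Because the rate is constant at steady state,
the metabolized amount per void is rate × interval rather than a time
integral; a quadrature would only differ for non-steady configurations,
which are out of scope.

## Arterial closure

The instantaneous-equilibrium assumption does not by itself fix the
arterial concentration in terms of the air level. Two closures are offered:

- `equilibrium` (default): `C_art = P_blood_air × C_inh / 1000`, the direct
  reading of assumption 2 (the 1000 converts mg/m³ of air to mg/L).
- `mass_balance`: the standard steady-state lung balance
  `C_art = (Q_alv C_inh/1000 + Q_card C_ven) / (Q_card + Q_alv/P_blood_air)`,
  with the mixed venous return `C_ven` closed self-consistently: at steady
  state non-metabolizing tissues return blood at `C_art`, while the liver
  returns blood depleted by its Michaelis–Menten extraction
  (`Q_l (C_art − C_vl) = Vmax C_vl/(Km + C_vl)`, solved by `brentq`); the
  outer fixed point is also a bracketed root search on `[0, equilibrium]`.

The equilibrium closure is deliberately simple and over-predicts uptake
(it ignores that ventilation limits delivery); the mass-balance mode is
always below it. Both are monotone in the air concentration, so the
inversion is well-posed in either mode.

## Inversion

`invert_air_concentration` exploits strict monotonicity: the upper bracket
doubles from 1 mg/m³ until the forward value exceeds the observation, then
`brentq` polishes to relative tolerance 1e-9. Observations at or above the
metabolic ceiling `f_ttma Vmax × 180 × (142.11/78.11) / void volume` raise
`SaturationError` — no finite exposure explains them. An observation of
exactly zero maps to zero without a search.

Cohort estimation inverts per child (each child's age, weight and urinary
creatinine substituted into the physiology template) and then averages;
this matters because the inversion is nonlinear and the tt-MA distribution
is strongly right-skewed, so invert-then-mean and mean-then-invert differ.
A `pooled` mode that inverts the cohort-mean tt-MA once is retained for
comparison. Sample moments use the n−1 denominator; a single-child cohort
reports SD 0.

## Parameters

All PBPK constants live in a TOML file (`[compartments.<name>]`,
`[metabolism]`, `[physiology]`, `[constants]`); every numeric key admits a
`<key>_source` provenance string, and the run log prints all of them so
placeholder values are never silently mistaken for literature values. The
shipped defaults are illustrative mid-range values for a ~27 kg child
(blood:air partition 8.19, cardiac output 2.76 L/min, alveolar ventilation
2 L/min, liver flow ≈ 26% of cardiac output, Km 0.35 mg/L, Vmax 0.30
mg/min, void volume 0.15 L). `f_ttma`, the molar fraction of metabolized
benzene excreted as tt-MA (default 0.039, i.e. single-digit percent), is
the dominant scaling uncertainty of the whole inversion: it multiplies the
reconstructed air concentration almost exactly inversely in the first-order
regime. `t_half` is carried in `MetabolismParams` for completeness but the
steady-state chain never uses it. No test asserts an absolute urine or air
value computed from the defaults; correctness is established by round-trip,
limit and monotonicity properties instead.

## Exposure and risk conventions

`CE = (C·ET·EF·ED)/(1440·AT)` with `AT = ED × 365`, under which convention
ED cancels and CE is just C times the fraction of time exposed. The
operator precedence (denominator `1440 × AT`) is fixed by checking that the
4 h/day and 8 h/day scenarios reproduce their published exposures
(0.80 and 1.60 mg/m³ from C = 5.85).

Presentation follows risk-assessment practice and is applied consistently:
CE is printed at 2 decimals and the hazard quotient is computed from that
rounded CE (so a reader recomputing HQ from the printed table gets the
table's own value: 1.60/0.03 = 53.3, where the unrounded CE would give
53.4); cancer risks are printed per 1000 exposed at one significant figure
(e.g. 12.48 per 1000 presents as 10). Raw unrounded values are always
carried alongside in `RiskResult` and the CSV/JSON reports.

The lifetime scenario's chronic exposure can be overridden
(`scenario_c_ce_override` / `--scenario-c-ce`): external exposure
calculators apply age-dependent adjustments that the plain averaging
formula does not capture, and the override carries such a value through the
risk arithmetic unchanged rather than guessing at its derivation.

Population burden multiplies the exposed head-count (workshops × children
per workshop) by the per-capita risk interval *at its presented precision*,
rounding expected cases to the nearest integer — matching how such numbers
are quoted.

## Synthetic data

`generate_cohort` emulates the structure of the motivating biomonitoring
sample: 41 children aged 6–12, each censored below the 0.06 mg/L LOQ with
probability 23/41 (censored values uniform on (0, LOQ) — their
distribution is irrelevant to retained-set statistics), quantifiable
children flagged abnormal-ACR with probability 3/18 (their tt-MA drawn from
the same distribution, as no difference is reported), and retained tt-MA
lognormal with (µ, σ) moment-matched to mean 0.81 / SD 0.83 mg/L:
µ = ln(m²/√(m²+s²)), σ² = ln(1+s²/m²). Ages are uniform; weight and height
follow a crude linear growth reference whose only asserted property is
monotonicity in age. All randomness flows through one integer seed of
`numpy.random.default_rng`.

The frozen 41-record fixture (`fixture_cohort_41`, shipped as a CSV)
encodes the composition exactly — 23/3/15 — with 15 retained values
constructed once from moment-matched lognormal quantiles plus a
two-parameter power adjustment (`c·x^p`, solved by root finding) so their
sample mean and SD are 0.81 and 0.83 at two decimals (n−1 convention), all
above the LOQ.

What passing tests on synthetic data do *not* show: real cohorts have
correlated age/anthropometry/creatinine, repeat-void variability,
non-lognormal contamination and background (traffic, biomass) tt-MA
sources; the generator models none of these, so recovery results here
bound only model-internal, not field, error.

## Numerical choices and degenerate inputs

- Root searches use `brentq` with near-machine relative tolerance; brackets
  are constructed to provably straddle (monotonicity for the inversion,
  the equilibrium bound for the lung balance).
- `t = ∞` is accepted by the filling curve and returns the asymptote
  exactly.
- Filtering order is fixed: censoring first, then the renal rule, so a
  record failing both counts as censored and the three counts always
  partition the input.
- Empty retained cohorts raise `EmptyCohortError`; the pipeline still
  writes the exclusion report first.
- The moment-matched lognormal for the study targets has excess kurtosis
  ≈ 40, so its sample SD converges slowly (≈3% relative sampling error at
  10⁴ draws); the convergence test uses 10⁶ draws.

## Problem sizes

The test suite and acceptance script run end-to-end in a few seconds on one
CPU: property tests use 100 random parameter draws, the recovery check a
200-child simulated cohort (GSD 1.5 noise), and the moment-convergence
check 10⁶ lognormal draws.

## Known limitations

- Steady-state only: no transient ODE simulation, no multi-day exposure
  patterns, no dermal or oral routes, and a single lumped tt-MA yield
  rather than full metabolite speciation.
- The shipped parameter defaults are placeholders; reconstructed absolute
  air concentrations are only as good as the supplied constants, with
  `f_ttma` the dominant lever.
- The hazard quotient and unit-risk machinery take RfC and IUR as given
  constants; no uncertainty-factor derivation or probabilistic risk
  characterization is attempted.
- Expected-case burdens treat the rounded per-capita risk as exact and
  assume every child in the head-count is exposed at the scenario level.
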