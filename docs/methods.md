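# Methods

`fiscalfood` simulates a product-specific sales tax on palm cooking oil in a
small open economy and traces its consequences through five coupled layers:
a multi-household computable general equilibrium (CGE) core, a fatty-acid
nutrition pathway, a serum-cholesterol-driven cardiovascular outcome module,
a cohort-component demographic projection, and direct land-use-change (dLUC)
greenhouse-gas accounting.  This note records the model's assumptions, the
defaults that matter, the synthetic-data design, and the numerical choices.

## Economic core

**Within-period equilibrium.**  Production is Leontief in intermediates over
a CES value-added nest: a CES labour composite of unskilled and skilled
labour (substitution elasticity 1.5) combined with capital and, for primary
crops, land (elasticity 0.8).  Trade follows the Armington convention: a CES
composite of domestic goods and imports (elasticity 2.0) on the demand side
and a CET split of output between domestic sales and exports (elasticity
2.0) on the supply side, with fixed world prices and a flexible real
exchange rate.  Private demand is an Almost Ideal Demand System (AIDS) per
regional household, evaluated with the full translog price index anchored so
benchmark budget shares are reproduced at unit prices.  The consumer price
index (Laspeyres at base household weights) is the numeraire.  The system is
solved as a square nonlinear system in log activity levels, log domestic
prices, log factor prices, the log exchange rate and one closure variable,
by damped Newton iteration with a finite-difference Jacobian (tolerance
1e-11 on scaled residuals, bounded steps, monotone line search, with a
trust-region hybrid fallback for narrow valleys).  The capital-market
equation is omitted; its residual value — Walras's law — is computed at
every solve and must stay below 1e-6 of nominal GDP, which makes any
violation of the budget identities detectable rather than silently absorbed.

**Closures.**  The counterfactual uses a balanced closure with a fixed
government-consumption-to-absorption ratio and savings-driven investment.
The policy run uses an iso-government closure: real government consumption
and government savings follow the counterfactual path, and additional sales
tax revenue is returned through a uniform additive reduction in household
direct-tax rates (non-distorting in this model).  Three iso-consumption
variants replace the tax recycling with per-household lump-sum transfers
that hold (1) nominal household budgets or (2) real household consumption at
the counterfactual while the government's nominal budget is maintained, or
(3) both household and government real consumption.  A uniform tax-rate
shift combined with per-household transfers would be collinear (an
income-proportional transfer vector replicates it exactly), so the transfer
variants keep government savings endogenous.

**Dynamics.**  The model is recursive, not forward-looking.  Capital follows
`K(t+1) = (1 - delta) K(t) + I(t)` with depreciation `delta = 0.05`/yr on a
base stock calibrated steady-state-consistently as `I0 / (g + delta)`;
capital services scale with the stock.  Labour endowments scale with
health-corrected working-age person-years (participation default 0.72,
retirement age 65, fixed skill split).  Two per-period shifters are solved
on the counterfactual: a Hicks-neutral productivity factor targeting 3.9%
p.a. real GDP growth (secant iteration, 1e-9 relative) and a nominal anchor
targeting 6.2% p.a. nominal growth (exact by homogeneity: all solves are
carried out in numeraire units and rescaled).  Both shifters are frozen and
reused in policy runs.

**Health feedback.**  Within each policy period the equilibrium, the intake
and biomarker changes, the clinical outcomes, and the labour/hospital-cost
feedbacks are iterated to a fixed point (relative change below 1e-7, at most
50 sweeps; in practice 2–4).  The hospital-bill deviation from the
counterfactual is government-financed by default (a config switch moves it
to households) and accrues to households as provider income, keeping the
accounts closed.  With the feedback frozen — the biomarker change forced to
zero, baseline population, labour and hospital costs — the run defines the
pure sales-tax pathway; the health pathway is the per-indicator difference,
additive by construction.

## Nutrition and biomarker pathway

Household commodity consumption maps to per-capita daily energy through
commodity energy densities (kcal per currency unit) and to saturated (SFA),
monounsaturated (MUFA) and polyunsaturated (PUFA) fatty-acid energy via
per-commodity energy fractions.  Energy-share changes are measured in
percentage points against the same-period counterfactual (the run being
differenced), not against the lagged period; this makes the zero-policy run
identically zero and matches the reporting convention of the indicator
tables.  The population-mean Total:HDL cholesterol ratio responds linearly,

    dC = 0.003 dSFA - 0.026 dMUFA - 0.032 dPUFA,

per percentage point of energy share, with configurable confidence bounds
used by the biomarker sensitivity suite.  Energy-level changes are tracked
but only compositional changes enter the cholesterol equation.
Intra-household heterogeneity is carried by 10 support points (strata) with
fixed frequencies; the mean change shifts every support point additively, so
scenario strata are the baseline strata displaced by the current
baseline-relative dC.

## Clinical outcomes

Risk functions map the cholesterol ratio to annual incidence and excess
mortality probabilities for myocardial infarction (MI) and stroke per age
band, gender and rural/urban location.  Lookup tables are built by Monte
Carlo: for each cell and each of 11 support values spanning the ratio
interval [2.0, 7.0], the mean risk over 10,000 simulated individuals drawn
from a normal distribution recentred at the support value with the cell's
standard deviation.  Degree-10 polynomials interpolate the 11 table values
exactly (Vandermonde solve with one step of iterative refinement, domain
normalised to [-1, 1] for conditioning, outputs clipped to [0, 1]).
Outcomes per cell are frequency-weighted expectations over the strata;
premature deaths are capped at the cell population.  Years lost to
disability are undiscounted person-years: cases x disability weight x
duration, with an acute MI duration (0.04 yr x weight 0.04) and a chronic
stroke duration (3 yr x weight 0.30, capped at the remaining horizon) —
this reproduces the characteristic pattern of tiny MI and large stroke
disability burdens.  Caregiver time (0.74 work, 1.09 leisure person-years
per stroke case) and patient worktime losses are corrected for workforce
participation; work losses feed back into labour endowments, leisure losses
are reported only.

## Demography

Population is tracked by region-location, thirteen five-year age bands
(10–14 through 70+; younger children are outside the adult biomarker
pathway and are abstracted into the first band's inflow) and gender, with an
annual step: one-fifth-per-year graduation between bands, fertility applied
to female reproductive bands, background mortality plus cardiovascular
excess deaths allocated by modelled cell, and zero-national-sum migration.
The accounting identity `pop(t+1) = pop(t) + births - deaths + migration`
holds exactly per region-location and is exposed through a step ledger;
averted deaths persist and age, generating the person-year ledgers that the
indicator tables report.

## Land use and emissions

Crop areas are proportional to the equilibrium land-factor allocation
across primary-crop activities (land is fixed and fully employed, so total
area is conserved; at the benchmark, areas equal output times the yield
coefficients).  The stated alternative — areas always equal to output times
a fixed yield — cannot simultaneously conserve land off the benchmark under
CES factor demand, so factor-based allocation is the primitive and yields
define the benchmark mapping.  Net per-crop area losses are allocated to
net gains proportionally (no transition-preference data) and each converted
hectare emits the antisymmetric crop-to-crop coefficient, derived from
per-crop carbon stocks with oil palm as the high-stock perennial: taxing
palm oil pushes land out of oil palm into lower-stock annual crops, a
positive net emission.  Only direct LUC is computed.

## Synthetic data: what it emulates and what it does not

The original analysis calibrated to a national social accounting matrix,
household consumption and socio-economic surveys, a health examination
survey, official population projections and national LUC coefficients; none
of these are distributable.  The generator produces seeded stand-ins with
the structure the method assumes, plus a known ground truth for recovery
tests:

- **SAM**: a consistent circular-flow fixed point over 10 commodities
  (including palm cooking oil, other edible oils, the oil-palm crop and two
  further primary crops), 10 activities, four factors, four regional
  households, government, savings-investment and the rest of the world;
  balanced to machine precision by construction.  A full-size configuration
  (49 commodities, 9 households) is available behind `ModelDimensions.paper_scale()`.
- **Demand system**: regular AIDS parameters whose implied own-price
  elasticities fall around -0.9 to -1.0, with two deliberate anchors: the
  palm-oil own-price elasticity is set to -0.95 and the cross-price
  elasticity of other edible oils with respect to the palm-oil price to
  +0.20.  The substitution from palm oil toward polyunsaturate-dense oils
  is the pivotal mechanism of the health pathway: with weak or zero
  substitution, halving palm oil removes MUFA/PUFA energy along with SFA and
  the cholesterol ratio *rises* — the cross-price sensitivity suite spans
  0.00–0.25 precisely because the sign of the health impact hinges on it.
  The default sits where the protective substitution operates.
- **Diet**: palm oil contributes about 4% of dietary energy (roughly
  three-quarters of edible-oil energy), with fractions 0.49/0.37/0.10
  (SFA/MUFA/PUFA) for palm oil versus 0.13/0.27/0.58 for competing oils;
  densities are rescaled per household to a 2,000 kcal/day base diet.
- **Biomarkers and risks**: normal Total:HDL distributions with age- and
  gender-specific means (rising from ~3.2 to ~4.1 across bands, sd ~0.7)
  and bounded logistic risk functions rising steeply with age; stratum
  support points are decile mid-quantiles of the pooled household normal.
- **Noise model for recovery tests**: multiplicative lognormal noise on
  nonzero SAM cells (structural zeros preserved) and additive noise on
  off-diagonal cross-price and income elasticities, so symmetry, adding-up
  and Engel aggregation fail whenever noise is positive while own-price
  signs survive.

What passing tests do **not** show: the synthetic economy reproduces the
mechanism and sign structure of the policy experiment, not the published
magnitudes — those depend on the real national datasets.  On this economy
the 50% intake target requires a sales tax near 110%, roughly double the
published Thai figure, because the synthetic demand system and budget
shares differ from the Thai calibration.

## Calibration machinery

- **SAM balancing** minimises the generalized Kullback–Leibler divergence
  `sum(a log(a/q) - a + q)` subject to row-equals-column balance, solved
  exactly on the entropy dual (`a_ij = q_ij exp(lam_j - lam_i)`, Newton on
  the multipliers); a balanced prior is a fixed point, which the plain
  `a log(a/q)` form would not satisfy.  Fixed row/column targets reduce to
  biproportional (RAS) scaling, the cross-entropy solution for given
  margins.  Structurally infeasible patterns (an account that receives but
  cannot pay) are rejected with the offending account named.
- **AIDS posterior**: inverting the standard linear-approximate elasticity
  formulas at base shares gives signed priors, so the divergence is the
  precision-weighted squared deviation (Gaussian cross-entropy) rather than
  the KL form used for the non-negative SAM; the constrained minimum is the
  exact KKT solution of an equality-constrained least-squares problem —
  no iteration, constraints satisfied to machine precision.  Because truth
  lies in the constraint set and projection is non-expansive, the posterior
  is never farther from the truth than the prior in the weighted norm.

## Numerical conventions and degenerate inputs

- Tolerances: constraint residuals 1e-8; Newton residuals 1e-11; growth
  targeting 1e-9 relative; health fixed point 1e-7; intake targeting 0.1%
  relative, found by bisection on the ad-valorem bracket [0, 5] followed by
  secant refinement.
- Determinism: every stochastic element flows from a single integer seed
  through independent `SeedSequence` channels; identical configuration is
  bit-reproducible, and a zero-magnitude policy reproduces the baseline's
  exact floating-point path (warm starts are chosen by initial residual so
  the solver returns an already-converged point untouched).
- Degenerate inputs: dimension minima are enforced (6 commodities, 2
  households, 13 age bands, 2 strata, 2 periods); zero budget shares, zero
  total energy, duplicated interpolation nodes, non-bracketing coefficient
  bounds, out-of-grid retirement ages and infeasible balances raise typed
  errors; biomarker support points outside [2, 7] are clamped with a
  logged count; excess deaths are capped at cell populations with a warning.

## Known limitations

- No intertemporal optimisation, no unemployment, no disease-state
  transitions after incidence, no discounting or age-weighting of
  disability person-years, no indirect land-use change, and no monetised
  externality valuation.
- Caregiver leisure losses are reported un-valued and do not enter the
  economy.
- The first age band aggregates all pre-adolescent inflow; child-nutrition
  pathways are out of scope.
- Default problem sizes (10 commodities, 4 households, 20 annual periods)
  are the package's desk-scale configuration; all modules accept the
  full-size index sets.
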