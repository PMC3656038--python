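# Methods

## Model structure and assumptions

The core is a linear four-pool compartment model of topsoil (0–30 cm)
organic carbon, advanced daily. Fresh inputs enter the labile and
resistant residue pools; decomposed residue carbon is partly transferred
to the light SOC pool, decomposed light carbon partly to the heavy SOC
pool, and the heavy pool decomposes to CO₂ only. Reported "SOC density" is
the total over all four pools (at initialisation the residue pools are
empty, so it equals light + heavy).

The daily update is, in order: add the day's inputs to the residue pools;
decompose every pool by the exact exponential factor
`1 − exp(−K·f_env)`; route the decomposed carbon by the transfer
fractions. Using the exponential factor rather than the forward-Euler
`K·f_env` makes the operator unconditionally stable and equal to the
continuous solution for an isolated pool, so half-life identities hold
exactly. The fixed within-day order makes the operator a single
unambiguous affine map `x → A(f_env)·(x + u)`, which is what the
matrix-power oracle in the tests evaluates, and gives closed forms for the
steady state (`(I − A)x = A u`).

Two parameter sets are built in. The calibrated default uses a heavy-pool
rate of 2.6×10⁻⁵ d⁻¹ (73 y half-life) and a light→heavy transfer of 0.3;
the pre-calibration variant uses 1.8×10⁻⁵ d⁻¹ (105.4 y) and 0.45. The
sources we follow list both a 73 y and a 105.4 y figure for the heavy pool
in different places; we take the calibrated table as authoritative and
keep the other constructable via `DecompositionParams.original()`.

Residue-pool rate constants are derived from half-lives of 0.1 y (labile)
and 2.3 y (resistant). All rate↔half-life conversions use 365.25 d/y —
the only year length that reproduces all three tabulated half-lives (7.6,
73, 105.4 y) on rounding — while the simulation calendar itself uses
365-day years with no leap days.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| `k_light` | 2.5×10⁻⁴ | d⁻¹ | light-pool rate (7.6 y half-life) |
| `k_heavy` | 2.6×10⁻⁵ | d⁻¹ | heavy-pool rate (73 y) |
| `f_labile_light`, `f_resistant_light` | 0.30, 0.45 | – | residue → light transfers |
| `f_light_heavy` | 0.30 | – | light → heavy transfer |
| residue/yield ratio | 1.5 | – | wheat, harvest index ≈ 0.4; not a tabulated source value |
| root fraction | 0.40 | of residue | root mass share returned regardless of retention |
| carbon content | 0.45 | – | residue and root dry mass |
| retention | 0.95/0.83/0.705 | – | QLD / WA / NSW+VIC+SA stubble retained |
| residue split | 0.59 labile | – | RothC-style DPM/RPM precedent; configurable |
| spin-up | 100 | y | recycled forcing, rescaled to measured SOC |
| ensemble | 300 runs, ±10 % input | – | empirical 95 % CI |

Retention applies to above-ground residue only; root carbon is always
returned (the alternative — retention on roots too — is not supported by
the stated root contribution being a biomass estimate, not a management
outcome). Manure inputs are fixed at zero. Retention rates and cropland
area are held constant over the simulation period.

## Environmental rate modifier

The sources assert climate control of decomposition without giving
functional forms, so the modifier is a package-level choice with a neutral
default: `f_env ≡ 1`, meaning the tabulated rate constants apply as-is.
An optional climate-driven mode multiplies a Q10 temperature response
(Q10 = 2, normalised to 1 at 25 °C) by a linear soil-moisture response
(relative bucket water content, floor 0.05, 1 at saturation; one-bucket
balance with 0.9 d⁻¹ carry-over and 60 mm capacity). Both responses are
monotone and non-negative; at the reference temperature with saturated
moisture the modifier is exactly 1. All headline runs use neutral mode.

## Calibration and evaluation

Calibration is an exhaustive Cartesian grid search over the five key
parameters (`k_light`, `k_heavy` and the three transfer fractions),
minimising the absolute value of the mean deviation Σ(Pᵢ−Oᵢ)/n pooled over
all observations of all site trials, with deterministic lexicographic
tie-breaking. The signed-bias objective is kept because it is the
procedure the accounting is built on, but it is weakly identifying:
distinct parameter combinations can produce near-zero pooled bias, so
under observation noise the grid winner can sit one step from the
generating truth even when the truth is on the grid. The tests assert
exact recovery in the noiseless case and within-one-step recovery at 1 %
and 5 % observation noise.

Skill statistics: RMSE (absolute units; a normalised variant 100·RMSE/Ō is
available behind a flag), relative mean deviation (%), model efficiency
EF = 1 − Σ(O−P)²/Σ(O−Ō)², and OLS of predictions on observations with
two-sided t-tests of slope = 1 and intercept = 0 at α = 0.05. Because
observations appear as the regressor, measurement noise attenuates the
fitted slope below 1 even for a perfect model — visible in the synthetic
validation driver and expected.

Depth harmonisation multiplies 0–10 cm measurements by 2.35 and 0–20 cm
measurements by 1.32 to estimate the 0–30 cm density; the larger
coefficient belongs to the shallower layer, consistent with cumulative
depth distributions of SOC.

## Regional engine

A region is simulated as a single unit (one climate series, one yield
series, one retention fraction). Each Monte Carlo member draws one grid
cell's soil covariates (uniform over cells — an empirical PDF, since no
distribution family is given for the soil grids) and one input multiplier
(uniform on mean ± 10 %), then repeats spin-up and simulation; members are
vectorised through a batched engine so the 300-run, 150-year ensembles run
in seconds. Decade stock change is computed from start- and end-of-decade
densities times area, so decadal changes telescope exactly to the
full-period change; decade densities and inputs are within-decade means.
Belt aggregation sums areas and stock changes, area-weights densities, and
sums the regional CI bounds for stock-change intervals (the convention the
published belt row follows; it is conservative in treating regional errors
as comonotone). Ensembles propagate soil and input uncertainty only, not
parameter uncertainty.

## Synthetic data

The generators emulate the study conditions rather than any particular
dataset: daily temperature as a southern-hemisphere sinusoid (amplitude
7 °C, Gaussian noise sd 2.5 °C) around an annual mean drawn from
16.8–21.4 °C; rainfall from a two-state Markov occurrence chain
(P(wet|dry) = 0.25, P(wet|wet) = 0.55) with gamma amounts (shape 0.8)
scaled to an annual total drawn from 467–685 mm; yields rising linearly to
double the starting level (1 Mg ha⁻¹) across the 50-year span with
mean-corrected lognormal noise (CV 0.25); soil grids with SOC densities
uniform on 23–36 Mg C ha⁻¹; five regions with the published belt areas
(summing to 15.08 Mha). Site-trial observations get multiplicative
Gaussian noise and are depth-degraded by dividing the 0–30 cm truth by the
depth coefficients, making conversion exactly invertible at zero noise.

What the generators do *not* emulate: spatial autocorrelation of soils and
climate, drought-driven yield–climate covariance, land-use history, or
erosion/leaching losses. Passing tests therefore demonstrate the internal
correctness and self-consistency of the machinery under realistic
magnitudes, not agreement with any measured regional budget; the synthetic
belt loses carbon early and stabilises as yields rise, qualitatively like
the real system, but its totals are properties of the fixture.

## Numerical choices

Trajectories accumulate CO₂ and input totals in float64 alongside the
state, keeping cumulative mass balance below 10⁻¹⁰ relative over 10⁴-day
runs. Spin-up recycles whatever forcing it is given cyclically and
rescales final pools by a common factor to the observed total (preserving
proportions); with zero spin-up years it returns the plain 0.25/0.75
split. The required-extra-input search brackets by doubling and solves by
bisection (Brent) to 10⁻³ Mg C ha⁻¹ yr⁻¹, returning 0 when the baseline
trajectory is already non-decreasing. The steady-state solve raises a
dedicated error when positive inputs meet a frozen (f_env ≤ 0) system.
Problem sizes in the analysis drivers and acceptance script — 300-member
ensembles, 100-year spin-up, 20–25-year trials, 3⁵ calibration grids —
are the package's standard configuration and complete in well under a
minute in total.

## Known limitations

- No nitrogen cycling, erosion, leaching, or crop-growth simulation;
  carbon input is strictly yield-driven.
- The environmental modifier's climate mode is a plausible monotone form,
  not a fitted response; neutral mode is the defensible default.
- Belt CI bounds assume comonotone regional errors (bound summation),
  which overstates interval width relative to independent errors.
- The grid calibration inherits the weak identifiability of the signed
  mean-deviation objective discussed above; a squared-error objective
  would identify more sharply but would change the procedure.
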