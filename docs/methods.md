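# Methods

## Model structure and assumptions

`biodyn` treats the whole fish as a single well-mixed compartment whose
metal concentration `Ct` (μg/g wet weight) balances dissolved uptake
against first-order losses:

    dCt/dt = ku·Cw_i − (ke + g + kp)·Ct

Uptake is proportional to the dissolved water concentration `Cw_i`
(μg/L); losses comprise elimination (`ke`, 1/d), growth dilution (`g`,
1/d — the burden is spread over an increasing body mass) and, in infected
fish, uptake by intestinal parasites (`kp`, 1/d), which is modelled as a
host efflux. The parasite infrapopulation is a second compartment fed by
the host concentration amplified by the host-to-parasite weight ratio:

    dCp/dt = kp·Ct·W/Wp − np·gp·Cp

The parasite loss term multiplies the individual growth-rate constant
`gp` by the number of parasites `np`, following the source formulation
verbatim; a `parasite_loss="gp"` option drops the `np` factor for users
who prefer a per-individual dilution reading (the two differ by the
factor `np` in the parasite loss rate, and the model makes no claim about
which is biologically correct). No organ-level (PBPK) structure, dietary
uptake route, temperature dependence or water-chemistry correction is
included: the model is deliberately minimal so that all parameters can be
derived from body weight and one metal descriptor.

## Exposure forcing

Water is renewed periodically and the dissolved concentration is held
constant within each renewal interval (half-open intervals `[T_j,
T_{j+1})`; an evaluation exactly at a renewal time belongs to the
interval that starts there). When a schedule provides both pre- and
post-renewal measurements, the per-interval value defaults to their
arithmetic mean, configurable to post-renewal only — the data only
constrain the interval value to lie between the two.

Because the forcing is piecewise constant, the linear balance has an
exact per-interval solution, evaluated as the recurrence

    C(T_{j+1}) = C(T_j)·e^(−λΔ_j) + (gain·F_j/λ)·(1 − e^(−λΔ_j))

with `λ` the total loss rate. The algebraically expanded summation form
is retained as a second code path solely for identity testing; the
recurrence is the production engine (the typeset expanded formula in the
source material has ambiguous summation bounds, so the recurrence is
taken as ground truth and verified against numerical integration).

For the parasite compartment the host-derived source `Cf_j = Ct·W/Wp` is
approximated as constant within each interval, sampled by default at the
interval start (configurable to the midpoint or the exact interval mean).
This approximation is first-order in the interval length; the test suite
demonstrates the error halving under grid refinement against the coupled
ODE oracle. The weight ratio `W/Wp` is held at its initial value by
default, exactly as the symbols appear in the source equations; a
`weight_dynamics="projected"` option recomputes both weights per interval
from the discrete growth law. Growth enters the kinetics as a continuous
rate inside exponentials while weight projection uses the discrete
`(1+g)^t` law, mirroring the dual usage in the source; at `g = 0.015`/d
the discrepancy between `e^{gt}` and `(1+g)^t` over 36 d is below 0.03 %.

## Numerical oracle

`ode_oracle` integrates the differential forms with classical fixed-step
RK4 under the same piecewise-constant water forcing, but drives the
parasite ODE with the *continuous* host solution. It is the independent
check on the analytical engines: the uninfected engines agree to ~1e-12
(both are exact for this linear system; discrepancies are pure
round-off), while the analytical parasite series converges to the oracle
first-order in the renewal-interval length. `ode_oracle_batch` vectorises
the uninfected case across configurations sharing one renewal grid.

## Parameterisation

Rates derive from weight `W` (g wet) and the covalent index χ = Xm²·r:

| quantity | formula | default constants |
|---|---|---|
| max. ventilation | `VRmax = 254.4e-3·(1e-3·W)^(−1/4)` L/g/d | coefficient 254.4e-3 |
| ventilation | `VR = Q_liver·VRmax/(Q_liver+VRmax)` | `Q_liver` = 99.14e-3 L/g/d |
| absorption efficiency | `log10(p/(1−p)) = 0.18·χ − 2.31` | slope/intercept per column |
| uptake | `ku = p·VR` | — |
| weight-corr. elimination | `log10(ke0) = 0.25·χ − 1.78` | — |
| elimination | `ke = ke0·W^(−1/4)` | W in grams |

Note the deliberate unit asymmetry: the ventilation allometry converts W
to kg via the printed `1e-3` factor while the elimination allometry uses
grams; both conventions are kept verbatim from the source
parameterisation. The QSAR logarithms are base 10 (the convention for
such regressions), switchable to natural log. All constants live in one
`ModelConstants` table so refitted coefficients can replace the published
ones without touching call sites. Covalent-index values per metal are
user-supplied — none are built in, since the source does not print them.

The QSAR refits (`AbsorptionRegression`, `EliminationRegression`)
back-calculate `p_i = ku_i/VR(W_i)` (excluding records with p outside
(0,1), with a warning) or `ke0_i = ke_i·W_i^{1/4}`, then run plain
ordinary least squares of the transformed response on χ. The reported
p-value is the two-sided test of zero slope from the usual t statistic.
No weighting or further exclusions are applied.

## Calibration

* `GrowthModel` minimises `Σ(W_obs − W0(1+g)^t)²` over `g` with a
  bounded deterministic scalar search on `g ∈ (−0.5, 1.0)` /d (tolerance
  1e-12); `W0` is fixed to the first observation by default or profiled
  analytically; a log-scale option reduces the fit to linear regression.
* `ParasiteUptakeModel` exploits linearity of the parasite solution in
  `kp`: `Cp(t) = Cp0·e^{−λ_p(t−T0)} + kp·S(t)` with `S` the unit-gain
  response, so the least-squares `kp` is a closed-form ratio of inner
  products. Negative estimates are clipped at zero with a warning. Both
  "all observations" and "endpoint only" modes are provided, since
  endpoint-only calibration is common when time courses are unavailable.
* `UptakeKineticsModel` jointly fits `(ku, ke)` of the uninfected host by
  bounded nonlinear least squares on the analytical solution. The two
  constants are separately identifiable only if the sampling window
  covers both the rising limb and the approach to plateau; with
  `λ·T ≳ 4`, 7 subjects × 5 times and 20 % lognormal noise, median
  recovery errors are under ~11 %.
* `whole_fish_from_muscle` applies a user-supplied linear tissue
  conversion; no coefficients are built in.
* Where a calibrated `kp` for one metal is reused for others (the
  standard practice when time-resolved parasite data exist for a single
  metal), the reuse should be recorded by the caller; the synthetic
  generator applies its single `kp` to all compartments it simulates.

## Scenario sweep

Ten named scenarios (S1, S2, A1–D2) combine multipliers on the uninfected
fish's absorption efficiency (A: ÷2, B: ×2) and elimination rate (C: ÷2,
D: ×2) with two infection-effect modes: Cd-like (infected uptake ×2,
elimination ÷1.7) and Co-like (uptake ÷2, elimination ×1.7). "n times
lower" is read as division by n throughout. Uptake multipliers act on the
absorption-efficiency fraction (ventilation is assumed unaffected by
parasitism), capping any modified efficiency at 1−1e-6 with a warning;
`kp` and `g` are never scenario-modified. The sweep summary reports, per
scenario group, compartment and time, the max/min ratio of predictions.

A caution on reading terminal spreads under stochastic forcing: a
fast-eliminating scenario's terminal concentration closely tracks the
last renewal interval's (random) concentration, so with per-interval
uniform draws the terminal host spread partly reflects forcing noise
rather than parameter sensitivity. The sensitivity comparisons in the
test suite and the acceptance script therefore evaluate the sweep at the
nominal constant exposure (80 μg/L, the midpoint of the fluctuation
range), where the spread ratios are structural: ×4.0 for the uninfected
host (A/B) versus ×3.71 (C/D), and ×43.6 versus ×38.6 for the infected
host (the infection-mode multipliers compound the factor-of-two grid to
nearly two orders of magnitude).

## Validation metrics

`performance_metrics` regresses measured on predicted concentrations
(simple least squares; r² and the slope p-value are direction-symmetric
for simple regression) and reports MAE and RMSE on the arithmetic
concentration scale. With fewer than 3 pairs or zero prediction variance,
r²/p are NaN with a warning while MAE/RMSE are still returned.
`bioconcentration_factor` is the per-subject parasite/host concentration
ratio summarised as mean ± sample SD (n−1 denominator), excluding
non-positive host values with a warning.

## Synthetic experiment generator

`SyntheticConfig` encodes the emulated study design: 36 days, renewal
every 3 d, dissolved Pb drawn uniformly per interval from 40–120 μg/L
(only the range is documented for the real experiment, so uniform is the
least-informative choice; a sawtooth within-interval decline is available
with a free decline fraction), 7 fish per group with weights from a
positive-truncated normal (10 ± 3 g), parasite counts per infected fish
from a rounded truncated normal (5.29 ± 2.21 control, 5.71 ± 3.77
exposed; floor of 1) and individual parasite weights of 1.62 ± 1.11 /
1.87 ± 1.13 mg. Measurements multiply the model truth by lognormal noise
with median 1 and CV 0.2 — a stand-in calibrated qualitatively to typical
tissue-analysis scatter, not a documented value. Background Fe/Cu/Zn
water concentrations default to nominal tap-water constants (25, 10,
60 μg/L) and are user-overridable. The generating kinetics use a
covalent index of 6.0 — an explicit synthetic stand-in in the range of
soft-metal descriptors, chosen once — with `g = 0.015`/d,
`gp = 0.021`/d and `kp = 1.36e-3`/d.

Every draw flows from one integer seed through named independent
substreams, so regeneration is bit-identical and each emitted table
embeds the config hash and seed. What passing tests on these data show:
the pipeline recovers its own generating parameters and validates its own
predictions under the stated noise. What they do not show: fit to any
real measured concentration, inter-individual kinetic variability beyond
weight, non-lognormal measurement error, or within-interval exposure
dynamics beyond the optional sawtooth.

## Problem sizes and numerical settings

The test suite and acceptance script run at the study's natural scale
(12 intervals × 36 d, 7 subjects, 100-configuration oracle comparisons,
200-replicate noise studies), completing in seconds. Oracle steps are
1e-3 d for equivalence checks and 5e-3–1e-2 d elsewhere; the analytical
engines are step-free. Degenerate inputs (non-positive total loss rate,
weights, or interval structure) raise typed errors rather than returning
NaN; ties at renewal times resolve to the starting interval.

## Known limitations

* The parasite compartment's piecewise forcing makes its analytical
  series first-order accurate in the renewal interval; for fast host
  dynamics relative to the renewal period, prefer `cf_sampling="mean"`
  or the ODE oracle.
* The `np·gp` loss convention ties parasite turnover to infrapopulation
  size; with large `np` this implies implausibly fast dilution, which is
  why the `gp`-only switch exists.
* The QSAR parameterisation explains only part of the variation in
  absorption efficiency in the underlying data compilations; derived
  `ku`/`ke` are order-of-magnitude tools, not precision estimates.
* Joint `(ku, ke)` calibration degenerates to ratio-only identifiability
  when observations sit near steady state.
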