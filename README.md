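# biodyn

One-compartment biodynamic modelling of metal accumulation in fish and
fish–parasite systems under fluctuating aqueous exposure.

## The problem

Fish are standard bioindicators of metal pollution, but intestinal
parasites — acanthocephalans in particular — accumulate metals far beyond
their host's levels and thereby alter the host's apparent burden.
Interpreting bioaccumulation data from infected fish therefore needs a
kinetic model in which parasite uptake is an explicit loss pathway of the
host. `biodyn` implements such a model for waterborne exposure with
periodic water renewal (the concentration is held constant within each
renewal interval), parameterised mechanistically from fish weight and a
metal's covalent index, so it extrapolates across metals and fish sizes
without per-system calibration.

## The model

Uninfected host (whole-fish concentration `Ct`, μg/g wet weight):

    dCt/dt = ku·Cw_i − (ke + g)·Ct

with `ku` (L/g/d) the dissolved uptake rate constant, `Cw_i` (μg/L) the
water concentration in renewal interval *i*, `ke` (1/d) elimination and
`g` (1/d) growth dilution. Infected host: parasite uptake `kp` (1/d) adds
to the loss, and the parasite compartment is driven by the host
concentration rescaled by the host-to-parasite weight ratio:

    dCt/dt = ku·Cw_i − (ke + g + kp)·Ct
    dCp/dt = kp·Ct·W/Wp − np·gp·Cp

Because the forcing is piecewise constant, both compartments admit exact
per-interval solutions (an interval recurrence), which `biodyn` evaluates
analytically; a fixed-step 4th-order Runge–Kutta integrator of the
differential forms is kept as an independent oracle.

Rate constants derive from two quarter-power allometries and two
covalent-index (χ = Xm²·r) QSARs:

    ku = p·VR,  VR = Q_liver·VRmax/(Q_liver + VRmax),
    VRmax = 254.4×10⁻³·(10⁻³·W)^(−1/4),  log₁₀(p/(1−p)) = 0.18·χ − 2.31
    ke = ke,0·W^(−1/4),                  log₁₀ ke,0    = 0.25·χ − 1.78

Growth follows the discrete law `W_t = W₀(1+g)^t`. The package also
provides the ten-scenario sensitivity grid (absorption efficiency and
elimination varied by factors of two, combined with Cd-like and Co-like
infection effects), validation metrics (r², p, MAE, RMSE,
bioconcentration factors), least-squares calibration of `g`, `gp`, `kp`
and `(ku, ke)`, and a seeded synthetic-experiment generator shaped like a
36-day chub–acanthocephalan Pb exposure (renewal every 3 d, dissolved Pb
40–120 μg/L, 7 fish per group).

## Worked example

```python
import numpy as np
import biodyn as b

# rate constants for a 10 g fish and a metal of covalent index 6
params = b.derive_params(weight=10.0, covalent_index=6.0, g=0.015, kp=1.36e-3)
print(f"ku = {params.ku:.4g} L/g/d, ke = {params.ke:.4g} /d")

# a 36-day exposure, water renewed every 3 days, Pb fluctuating 40-120 ug/L
schedule = b.generate_exposure(b.SyntheticConfig(seed=1))
load = b.ParasiteLoad(n_parasites=5, Wp0=0.008, gp=0.021)
system = b.HostParasiteSystem(b.FishState(C0=0.0, W0=10.0), load)
series = b.simulate_infected(schedule, params, system, np.arange(0.0, 37.0, 6.0))
print(series.to_frame().round(3))
```

prints

```
ku = 0.004908 L/g/d, ke = 0.2951 /d
   time_d  host_conc_ugg  parasite_conc_ugg
0     0.0          0.000              0.000
1     6.0          1.202              2.533
2    12.0          1.131             10.710
3    18.0          1.353             13.026
4    24.0          1.383             16.475
5    30.0          0.974             18.255
6    36.0          1.014             19.338
```

The host reaches a quasi-steady concentration of roughly `ku·Cw/(ke+g+kp)`
(≈ 1.3 μg/g at 80 μg/L) that wobbles with the renewal-to-renewal water
concentration, while the parasites — fed by the host at the
weight-amplified source `Ct·W/Wp` and losing metal only through growth
dilution (`np·gp` ≈ 0.105 /d) — keep accumulating towards a level more
than an order of magnitude above the host, the pattern that makes
acanthocephalans sensitive accumulation indicators.

The growth-rate and parasite-uptake calibrations work the same way:

```python
t = np.arange(0.0, 37.0, 3.0)
res = b.fit_growth_rate(b.WeightSeries(t, b.project_weight(10.0, 0.015, t)))
print(res.summary())   # relative growth rate g = 0.015 /d  (W0 = 10 g, n = 13, SSR = 7.56284e-17)
```

A `biodyn` command-line interface exposes the same functionality
(`biodyn param`, `simulate`, `scenarios`, `fit-growth`, `fit-kp`,
`fit-rates`, `validate`, `synth`); run `biodyn --help`.

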