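# adcr — advection–diffusion capture–recapture

Spatial capture–recapture (SCR) estimates animal population density from
repeat detections of identified individuals at an array of detectors
(camera traps, hair snares, …).  Classic SCR assumes a bivariate-normal home
range, which breaks down when the landscape channels movement: rivers,
roads, and habitat edges make some places easy to cross and others nearly
impassable.  `adcr` implements a *mechanistic* SCR in which the home range
is the equilibrium of the animal's movement process itself, so that
population density and **landscape permeability** are estimated jointly from
ordinary capture–recapture data.  It is aimed at quantitative ecologists
working on density estimation and landscape connectivity.

## The model

An individual with activity centre μ moves by an Ornstein–Uhlenbeck-type
process: drift of intensity `c = exp(α₀)` toward μ plus a random walk whose
local intensity (permeability) is log-linear in landscape covariates,

```
D(x, y) = exp(β₀ + β·z(x, y)).
```

The probability density p of the individual's location obeys an
advection–diffusion equation with reflecting boundaries,

```
∂p/∂t = −c ∇·((μ − s) p) + ∇·(D ∇p),
```

whose equilibrium p*(s|μ) — the utilization distribution — depends only on
`γ₀ = β₀ − α₀` and β.  When D is constant (β = 0), p* is exactly the
bivariate normal with variance `exp(γ₀)`, recovering classic SCR.  Count
detectors observe Poisson detections with per-time-step intensity

```
λ_ijk = exp(g₀) · p*(s_j | μ_i),
```

and activity centres follow a homogeneous Poisson process with log density
ρ.  Marginalizing the unknown centres and undetected individuals gives a
full likelihood that is maximized by quasi-Newton; the PDE is discretized
on the covariate raster as a sparse Markov generator and solved once per
candidate centre (banded linear solve, cached across optimizer steps).

The package also provides the two standard comparison estimators under the
same likelihood machinery — basic SCR (`ln λ = g₀ + g₁‖s_j − μ‖²`) and SCR
with least-cost-path distance (edge cost `exp(g₂(z(s)+z(s'))/2)` on the
8-neighbour graph) — plus a movement simulator, home-range metrics
(overlap coefficient, 90% highest-density area), and an experiment harness.

## Worked example

```bash
python examples/03_fit_adcr.py
```

```
N=109, detected n=47, detections=80
converged: True   log-likelihood: -378.03
param       true      mle      se   95% CI
rho        -0.60   -0.887   0.184   (-1.247, -0.526)
g0          0.50    0.395   0.181   (+0.040, +0.749)
gamma0      1.00    1.252   0.270   (+0.723, +1.780)
beta_1      1.00    1.857   0.587   (+0.706, +3.008)
```

A 15×15 landscape with two habitat patches is surveyed by 25 count
detectors over 5 occasions; 47 of 109 simulated individuals are detected.
The fit recovers log density `rho`, log detectability `g0`, the log
diffusion/drift ratio `gamma0` (home-range size: `exp(γ₀)` is the
home-range variance in homogeneous habitat), and the permeability
coefficient `beta_1` — its positive estimate with a CI excluding zero
correctly identifies the patches as easier to move through.  The other
examples show home-range shapes under varying permeability
(`01_home_range_shapes.py`), full movement-based survey simulation
(`02_simulate_survey.py`), the three-estimator comparison experiment
(`04_compare_estimators.py`), and the plain-text file formats and CLI
(`05_files_and_cli.py`).

A thin command-line interface wraps the same functions:

```bash
adcr landscape --nx 50 --ny 50 --patches 5 --seed 1 --out cov.asc
adcr simulate --seed 3 --out survey/
adcr fit --traps survey/traps.txt --captures survey/captures.txt \
         --raster survey/landscape.asc --model adcr --out fit.json
adcr experiment --preset desk --seed 1 --out runs/
```

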