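# Methods

## Model

`adcr` couples two classical components.  The *population process* is a
homogeneous Poisson point process for activity centres over a rectangular
region 𝒮 with log density ρ: on the discretized landscape this is a discrete
uniform over cell centres with prior weight `a = h²` per cell.  The
*observation process* is a count detector: given an activity centre μ, the
number of detections of that individual at detector j per unit survey time
is Poisson with mean `exp(g₀) p*(s_j|μ)`, independent across detectors and
time.  The link between the two is the utilization distribution p*, derived
mechanically from movement rather than assumed Gaussian.

Movement is an Ornstein–Uhlenbeck-type process: drift `c(μ − s)` toward the
activity centre (site fidelity, `c = exp(α₀)`) plus a random walk whose
local intensity — the permeability `D(s) = exp(β₀ + β·z(s))` — is log-linear
in raster covariates z.  The location density follows the advection–
diffusion equation

    ∂p/∂t = −c ∇·((μ − s) p) + ∇·(D ∇p)

with zero-flux (reflecting) boundaries, and p*(·|μ) is its equilibrium.
Because only the balance of diffusion against drift matters at equilibrium,
(α₀, β₀) enter only through γ₀ = β₀ − α₀; the model estimates (ρ, g₀, γ₀, β).
With β = 0 the equilibrium is the bivariate normal with variance exp(γ₀)
per axis, so basic SCR is the homogeneous special case.

The diffusion term is written in Fickian (conductance) form `∇·(D∇p)`, the
circuit-theory reading of permeability: its stationary density decays like
`exp(∫ v/D)` along each axis, so decay is slow through permeable habitat and
home ranges skew toward high-permeability patches, while nearly impermeable
cover (e.g. open water for a forest mammal) is avoided.  The alternative
Fokker–Planck form `Δ(Dp)` would concentrate equilibrium mass in *low*-
permeability habitat (stationary ∝ 1/D under pure diffusion), the opposite
of the home-range phenomenology this model targets.  One subtlety worth
knowing: for a patch far from the activity centre the 2-D equilibrium mass
on the patch need not be monotone in β (the stationary flux circulates when
v/D is not a gradient field); the monotone skew holds for patches within or
adjacent to the home range, which is the configuration that matters for
inference.

## Discretization

The operator is discretized on the covariate raster (cells of side h, rook
neighbourhood) as a continuous-time Markov chain generator Q: off-diagonals
are non-negative jump rates, rows sum to zero exactly, so conservation and
the reflecting boundary hold by construction.  Each face between cells L
and R carries conductance `Df = (D_L + D_R)/2` and drift velocity u
evaluated at the face; the jump rates use exponential-fitting
(Scharfetter–Gummel) weights,

    rate(L→R) = Df/h² · B(−u h/Df),   B(x) = x/(eˣ − 1),

which keeps rates positive for arbitrarily strong drift and — the reason it
is the default — makes the β = 0 equilibrium *exactly* the grid-renormalized
cell-centre Gaussian with variance exp(γ₀) (verified to machine precision in
the tests).  A first-order upwind weighting (`scheme="upwind"`) is provided
for comparison; it is positivity-preserving but only first-order accurate,
and its homogeneous equilibrium deviates visibly from the Gaussian
(overlap ≈ 0.89 on a 41×41 grid at exp(γ₀) = 4).

The equilibrium solves pᵀQ = 0, Σp = 1.  The system is banded (bandwidth =
grid width); it is solved by LAPACK's banded LU after pinning p = 1 at the
activity-centre cell and renormalizing — equivalent, for an irreducible
generator, to replacing one equation by the normalization constraint, but
it preserves bandedness.  Grids of ≤ 64 cells use a dense solve; a dense
smallest-singular-vector solve is the last-resort fallback.  Every solve is
residual-checked (‖pᵀQ‖∞ ≤ 1e−8·max|Q|) and validated against a dense
null-space oracle on small grids in the tests.

## Likelihood and fitting

With all cells as candidate centres, the full likelihood for n detected
individuals is

    ln L = −exp(ρ) Σ_m a (1 − e^{−Λ(m)})
         + Σ_i ln[ exp(ρ) Σ_m a Π_{j,k} Pois(y_ijk; λ_j(m)) ] − ln n!,

with Λ(m) = K Σ_j λ_j(m) and λ_j(m) = exp(g₀) p*(s_j|μ_m).  Individual
terms are computed in log space with log-sum-exp over centres.  K is an
*effort* multiplier: data collected as K equal occasions use K, while
movement-simulated surveys that aggregate T unit time steps into one stored
occasion use K = T, keeping g₀ on its per-time-step scale.  The −ln n! term
is retained so log-likelihoods are comparable across models; it does not
move the optimum.

One equilibrium solve per candidate centre is needed per evaluation; the
detector-column matrix `U[m, j] = p*(s_j|μ_m)` is cached per (γ₀, β), so
quasi-Newton steps that perturb only ρ or g₀ are nearly free.  Optimization
is L-BFGS-B with finite-difference gradients (step 1e−5, `ftol` 1e−10,
`gtol` 1e−6, unconstrained parameterization); standard errors come from the
numerically differenced observed information at the optimum, with Wald 95%
intervals.  Non-convergence and indefinite Hessians are flagged on the
result, never raised.  Starting values are crude moments: ρ from n and the
region area, g₀ from mean counts, γ₀ from the mean squared recapture
displacement, β = 0.

The comparison estimators share the likelihood skeleton and differ only in
λ: basic SCR uses `exp(g₀ + g₁‖s_j − μ‖²)` (half-normal, unnormalized, g₁<0
enforced by optimizing log(−g₁)), and SCR-LCP replaces the Euclidean by the
least-cost-path distance on the 8-neighbour lattice (diagonals √2 h) with
edge cost `exp(g₂(z(s)+z(s'))/2)`; positive g₂ means the covariate impedes
movement, the sign convention opposite to β.  The detection exponent of the
LCP variant is 1 by default and switchable to 2 (`lcp_exponent`), since
both conventions appear in the least-cost SCR literature.  For cross-checks
the euclidean variant can also run with a grid-renormalized Gaussian
surface (`surface="gaussian"`), which makes it the exact β = 0
reparameterization of ADCR — the tests require the two fits to agree to
1e−4.

## Movement simulator

The data-generating process for the simulation experiments is deliberately
*not* i.i.d. from the likelihood: it simulates temporally autocorrelated
movement.  Each unit time step propagates the location by the explicit
(forward-Euler) kernel `(I + δQ)^m`, with the sub-step δ = 1/m chosen as the
largest value satisfying the positivity condition `1 + δ Q_ii ≥ 0` with a
10% safety margin.  Rather than forming the m-step kernel, the simulator
draws every sub-step of the chain and records each m-th state — by the
Chapman–Kolmogorov equation this samples from exactly the same
distribution — in a numba kernel, which makes full-scale simulation
(50×50 grid, ~400 individuals, 5000 steps) a matter of seconds.  Long-run
occupancy frequencies are tested to converge to p* (total variation < 0.05
at 10⁶ steps on a 10×10 grid).

Detection happens only while an individual occupies a detector's cell:
counts per step are Poisson(exp(g₀)).  Individuals never detected are
censored, as in a real survey; the uncensored truth is retained separately.

## Study conditions and the synthetic-landscape generator

Baseline simulated surveys use a 50×50 unit-cell landscape with five random
habitat patches of 100–250 cells, covariate +0.5 on patches and −0.5
elsewhere; 81 count detectors on cells 9–41 at spacing 4; T = 5000 steps
after 100 burn-in; ρ ~ U(−3, −1), α₀ ~ U(−1, 0), β ~ U(−2, 2), with g₀ = −3
and β₀ = 1 fixed.  The sparse-data variant fixes ρ = −2, α₀ = −0.5, β = 2,
g₀ = −5 and removes every detector on low-permeability cells.  Patches grow
by seeded random accretion from a uniform seed cell (4-connected, overlap
rejected, bounded retries, deterministic per seed); patch count and the
area range are configuration, chosen so that |β| ≤ 2 visibly distorts home
ranges at these home-range sizes.

What the generator does *not* emulate: temporal variation in effort,
behavioural responses to capture, sex/age heterogeneity, open-population
turnover, and spatial density gradients.  Passing tests therefore
demonstrate correctness of the estimator under its stated movement model
and robustness to movement autocorrelation — not robustness to those
further field realities.

## Problem sizes used by the tests

Full 100-iteration replication of the simulation study with all three
estimators is an overnight single-CPU run (`adcr experiment --preset
paper`).  The default test suite instead runs: exact property checks
(machine-precision conservation, residuals, null-space and closed-form
oracles); five full-scale *simulation-only* iterations for the
detection-rate and detection-count summaries; a four-iteration
estimator-comparison on a 28×28 grid with T = 1500 (loose, scaled-down
tolerances); and twenty parameter-recovery fits on a 15×15 grid.  The
acceptance script simulates twenty full-scale baseline iterations
(simulation only, no fitting).

## Numerical choices and edge cases

- B(x) is evaluated by series for |x| < 1e−8 and decays to 0 for x > 500,
  avoiding overflow for arbitrarily strong drift (far cells on big grids).
- Utilization values are clipped at the smallest positive double before
  taking logs in the likelihood; a non-finite likelihood evaluates to −∞
  with a warning rather than raising inside the optimizer.
- Degenerate inputs: a 1×1 grid has generator [0] and point-mass
  equilibrium; γ₀ → −∞ home ranges collapse to the centre cell; empty data
  (no detections) evaluate the survey-exposure term only, and fitting
  requires n ≥ 1.
- Experiment iterations derive their seeds as `SeedSequence(master,
  spawn_key=(i,))`, so any subset of iterations reruns identically;
  per-iteration JSON checkpoints make runs resumable, and wall-clock
  columns are excluded from the aggregate CSV so it is bit-reproducible.
- HDA90 counts cells in decreasing density order until 0.9 of the mass is
  covered (value-based ordering makes ties deterministic); on a fine grid
  it matches the closed-form Gaussian highest-density area 2πσ² ln 10
  within 2%.

## Known limitations

- The likelihood uses every cell as a candidate activity centre; run time
  scales as (cells)² per movement-parameter change.  A 50×50 ADCR fit takes
  minutes per likelihood surface; thinning candidate centres would trade
  accuracy for speed and is not implemented.
- Detectors are snapped to raster cells; sub-cell detector geometry is lost.
- Constant effort per occasion only; varying effort and other detector
  types (binary proximity, multi-catch) are out of scope.
- Closed population, homogeneous density; no GPS-track integration.
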