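# Methods

## Model and inference problem

A metabolic network with `n` metabolites and `r` reactions is the ODE
system `dS/dt = STOI · v(S)`, with `STOI` the signed `n×r` stoichiometric
matrix and `v` the vector of rate laws (mass action or Michaelis–Menten;
units are arbitrary throughout — the algebra is unit-agnostic, with `J` in
inverse time and `C` in squared concentration). Adding Gaussian white noise
yields the Langevin equation `dS = f(S) dt + B dW` with constant diffusion
`B Bᵀ = 2D`. Linearized about a stable steady state `S*`, this is an
Ornstein–Uhlenbeck process whose stationary covariance solves
`J C + C Jᵀ = −2D`. The factor 2 in `B Bᵀ = 2D` is the unique scaling that
makes the simulated ensemble covariance converge to the solution of that
equation; it is verified numerically by the fluctuation-dissipation tests
(scalar OU variance `d/a`, 2-species covariance vs. the Bartels–Stewart
forward solve).

The inverse problem vectorizes the Lyapunov equation. Equation `(i,k)`
reads `Σ_b J_ib C_bk + Σ_b J_kb C_ib = −2 D_ik`, so the coefficient of the
unknown `J_ab` is `[a=i]·C_bk + [a=k]·C_ib`. Only the `p` entries allowed
by the sparsity pattern are unknowns; the pattern is derived from
stoichiometry (entry `(i,j)` admissible iff some reaction changes species
`i` and its rate depends on `j`: as reactant, as product of a reversible
reaction, or as declared modifier). Allosteric regulation invisible in the
stoichiometry must be supplied through the modifier lists. Vectorization
order is row-major over the pattern-true positions and is fixed in
`JacobianPattern.index_map`; every solver, exporter, and score uses that
single convention.

All `n²` equations are kept rather than collapsing to the `n(n+1)/2`
unique ones. With a symmetric `D` the `(i,k)` and `(k,i)` rows coincide, so
off-diagonal equations are effectively weighted 2× in least squares; with
an asymmetric perturbed `D` the duplicated rows carry different right-hand
sides and least squares averages them, which is exactly the symmetrization
the equation's derivation implies. A note on dimensions: `A` is `n²×p` and
`b` must have length `n²` — only `x` shrinks to length `p` under the
sparsity reduction.

## Solvers and hyperparameters

- **OLS** is solved through the SVD (`lstsq`), which coincides with the
  normal-equations form `(AᵀA)⁻¹Aᵀb` on well-conditioned input but does not
  square the condition number; rank-deficient systems return the
  minimum-norm solution with a logged warning.
- **TSVD** discards the `t` smallest singular triplets. The automatic rule
  is a relative threshold: `t = #{i : σ_i/σ₁ < 1e−8}`, motivated by double
  precision — on well-conditioned systems TSVD is then *identical* to OLS,
  and the two separate only when `A` is numerically rank-deficient.
- **TTLS** truncates the SVD of `[A | b]` to rank `p − t` and uses the
  closed form `x = −V₁₂V₂₂⁺`. Plain TLS (`t = 0`) is near-singular whenever
  `σ_p(A)` approaches the TLS residual `σ_{p+1}([A|b])`, which makes an
  automatic `t` essential. The auto rule first detects the consistent
  regime (`σ_{p+1} < 1e−10·σ₁`: TLS is exact, least truncation wins) and
  otherwise minimizes held-out prediction error by deterministic 5-fold
  cross-validation over all admissible `t`.
- **TIKH** minimizes `‖Ax − b‖² + λ‖x − x₀‖²` (penalty norm fixed at
  `m = 2`; the normal-equations convention is `AᵀA + λI`, solved via the
  augmented stack without forming `AᵀA`). `x₀` defaults to zeros. The
  default λ grid is 30 log-spaced points spanning `[σ_p², σ₁²]`. Two
  selectors are implemented: k-fold cross-validation (default, k = 5,
  deterministic folds, ties toward smaller λ) and the L-curve corner
  (discrete curvature of the log-log residual/solution-norm curve by finite
  differences, no spline; the standard monotonicity of both norms in λ is
  checked as a precondition). CV is the default because on these systems
  the L-curve corner frequently lands in the over-regularized regime at
  small data perturbations, where ridge should coincide with OLS;
  CV tracks that bias–variance optimum.
- LASSO and elastic-net penalties are deliberately out of scope: the zero
  pattern is already fixed by stoichiometry, so shrinkage of the remaining
  entries is counterproductive.

Conditioning is reported as `κ_A = σ₁/σ_p`. For numerically rank-deficient
`A` (a singular value below `σ₁·1e−300`, i.e. an exact zero at double
precision) `κ_A` is +∞ and the companion `κ_A_finite` — the ratio to the
smallest *non-zero* singular value — keeps log-scale plots finite.

## Synthetic data generator

`make_random_mass_action_network` emulates small, sparse, stable
mass-action pathways: a random permutation chain of uni-molecular
conversions guarantees connectivity, extra conversions are added up to the
requested density, a few bi-molecular condensations keep the dynamics
non-linear, a random subset of species receives constant influx, and every
species carries first-order exchange with an external pool. That exchange
term keeps the steady-state Jacobian column-dominant, hence
Hurwitz-stable — mirroring how real pathway models exchange mass with
fixed external metabolite pools. Rate constants are log-uniform
(conversions 0.2–5, condensations 0.2–2, influxes 0.5–2, exchange 0.3–3 in
arbitrary units), a range chosen to keep eigenvalue spreads moderate so
that ensembles equilibrate within tractable step counts. Candidates are
regenerated (bounded retries, fully seeded) until the steady state is
positive and converged, the Jacobian is stable, and the pattern satisfies
`p ≤ n(n+1)/2` so the inverse problem stays overdetermined. An optional
`max_kappa` rejection additionally constrains the conditioning of the
noise-free linear system; the benchmark protocol uses `max_kappa = 300` at
`n = 8`, matching the well-conditioned end of real mass-action pathway
models (condition numbers around 10³), which is the regime where the
reference degradation patterns are defined.

The control-condition fluctuation matrix is `D₀ = diag((ρ·S*_i)²)` with
`ρ = 0.05`: fluctuation amplitudes at 5 % of each steady-state
concentration keep the dynamics in the linear-response regime where the
Lyapunov relation holds. SDE integration uses Euler–Maruyama with
`dt = min(0.01/max|Re eig J|, 0.05)` (resolving the fastest relaxation
while staying far inside the stability region) and ensemble burn-in
`min(10/min|Re eig J|, 200)` (ten times the slowest relaxation, capped).
Covariance estimation follows the replicated-experiment design: `N`
independent realizations start *at* the steady state, run for the burn-in
time, and the `N` endpoints form the sample (unbiased `N−1` denominator,
exact symmetrization). Endpoint sampling — not time-averaging within one
trajectory — is what real replicate metabolomics measurements correspond
to. Concentration states are clipped at zero (logged, since frequent
clipping signals departure from the linear regime); linear test models are
flagged as abstract OU processes and run unclipped.

What the generator does *not* emulate: measurement error on individual
metabolites, missing values and imputation artifacts, non-stationarity,
correlated (off-diagonal) true fluctuations, and saturable kinetics in the
random networks (SBML models supply those). Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to every artifact of real metabolomics data.

## Perturbation protocol and scoring

Covariance imperfection is produced by re-estimating `C` from random
subsets of the `N` replicates (law of large numbers: smaller subsets drift
further from the full-`N` reference), measured as
`δC = ‖C_i − C₀‖_F/‖C₀‖_F`. Subsample covariances that lose positive
definiteness are used as-is — that degeneracy is precisely what inflates
`κ_A` in practice (a nearest-PSD repair exists but is off by default).
Fluctuation uncertainty is `D_i = (I + E)·D₀` with `E` a full matrix of
independent `N(0, σ²)` draws, no symmetrization by default; at `σ = 1` the
perturbed `D` is effectively fully randomized. Note that with a full `E`
the relative change is `δD ≈ σ√n`, so σ levels of 0.01/0.1/1 correspond to
δD of roughly 3 %/28 %/280 % at `n = 8`; the benchmark records the
measured δD of every draw.

Goodness is the `R²` (with slope and intercept retained) of ordinary
linear regression of the estimated pattern entries on the true ones — the
intercept is kept so a systematic offset from the origin, which would
invalidate entry-wise comparison, remains visible. Method pairs are
compared with the Mann–Whitney U test (exact for ≤20 per group without
ties, tie-corrected normal approximation otherwise). The benchmark grid
derives a deterministic seed for every (fraction, σ, repeat) cell from the
master seed, so any single cell is reproducible in isolation, and solver
failures are recorded as failed cells rather than aborting the run.

Observed behaviour on the well-conditioned synthetic model matches the
expected qualitative pattern: near-perfect recovery at `δC = δD = 0`,
`R² ≈ 0.8–0.95` for OLS/TSVD/TTLS at `δC ≤ 10 %` with small σ, strong
degradation by `δC ≈ 50 %`, insensitivity to σ = 0.01, and collapse of the
median `R²` under full fluctuation randomization (σ = 1). TSVD equals OLS
throughout this regime, as expected from the threshold rule; their
separation is a rank-deficiency phenomenon.

## Problem sizes

The shipped protocol uses: 50 random networks (`n = 3–12`) for the
noise-free recovery sweep; `N = 2000` replicates for ensemble covariances;
an `n = 8`, `max_kappa = 300` model with subsample fractions
{1.0, 0.45, 0.01} (measured mean δC ≈ 0 %, 5 %, 50 %), σ ∈ {0.01, 1}, all
four methods, and 100 repeats per cell for the robustness benchmark. These
sizes make the whole pipeline reproducible on a single CPU in minutes
while preserving every qualitative contrast the protocol is meant to
exhibit.

## SBML input

The reader supports SBML Level 2/3 kinetic models: compartments (kinetic
laws are divided by the species' compartment size), global and local
parameters, function definitions (inlined), assignment rules for
parameters (substituted to a fixed point), reversibility flags, and
modifier lists. Species with `boundaryCondition="true"` or
`constant="true"` are excluded from the dynamic state and folded into the
rate laws as fixed numbers, following the SBML convention for constant
metabolites. Dynamic species appearing in a rate law without stoichiometric
participation in that reaction are auto-registered as modifiers so the
sparsity pattern stays a superset of the true Jacobian support. Events,
algebraic and rate rules, and time/delay csymbols are rejected with named
errors: a model that cannot be represented exactly is not approximated.
Steady states are found by stiff-capable integration (LSODA, geometrically
growing spans up to `max_time = 1e4` by default, tolerance
`max|dS/dt| ≤ 1e−9`), with divergence reported as non-convergence rather
than an exception; Jacobians are central finite differences with step
`max(1e−6·|S_j|, 1e−8)`.

## Known limitations

- The TTLS truncation and Tikhonov λ selectors are data-driven defaults;
  no selector is uniformly best on ill-posed problems, and both are
  config-exposed along with the recorded per-run choices.
- `R²` against the true Jacobian is dominated by the largest entries; for
  stiff models (entry spreads of 10³–10⁶) small entries are effectively
  unscored. The stiffness ratio (max/min non-zero |J| over the pattern) is
  reported alongside for that reason.
- The Lyapunov relation itself is a linearization; at large `ρ` or for
  strongly non-linear models the ensemble covariance departs from the
  forward solve and the "true" Jacobian becomes state-dependent.
- Exact stochastic simulation (Gillespie), implicit SDE schemes, and
  parameter estimation are out of scope.
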