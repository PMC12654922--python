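# Methods

## Model

The simulated system couples a single membrane protein to two scalar fields
on a flat, static, periodic membrane patch, in the overdamped regime (no
momentum-resolved hydrodynamics).  State:
`Y = [X, q(x), θP, θI, θC(x)]`.

**Particle.** `dX/dt = M F_X + H_thm` with scalar mobility `M = I/γp`.  The
force is conservative, `F_X = −∂_X U`, where
`U = Ψ(X) + c0 ∫ Φ(x;X) q(x) dx`.  Potentials are pluggable:

* `zero`, `harmonic` (test/equilibrium use);
* `kernel` — `Φ(x;X) = ±η(x−X)` with the truncated Gaussian
  `η(s) = (k1/2πσ0²) exp(−|s|²/2σ0²)`.  The sign is exposed as the
  `attractive` flag and defaults to attraction (Φ = −η): a positive kernel
  entering the energy with a plus sign would be repulsive, which
  contradicts the affinity the positioning study describes, so attraction
  is the default and the sign is a configuration choice;
* `well_lattice` — Gaussian wells of depth `c2` and width `σ0` on a
  staggered (offset-row) lattice; with the default spacing L/3 on the 20×20
  mesh, the escape-study well center `[5/3, 1]` is an exact lattice site.

**Concentration.** `∂q/∂t = div(κ̄ ∇q) + div((q/γ) ∇Φ) + g_q`, a conserved
drift–diffusion equation.  The molecular drag is fixed by Stokes–Einstein at
the baseline temperature, `γ = θ0/κ̄`.  Noise (below) is in divergence form
and conserves `∫ q dV` to machine precision per draw.

**Temperatures.**  Membrane:
`C_C ∂θC/∂t = div(κCC ∇θC) − κCI(x;X)(θC−θI) + heat − κ0 (θC − θ_bath)`.
Protein/interface:
`C_P dθP/dt = −κPI(θP−θI) + F·M F`, and
`C_I dθI/dt = +κPI(θP−θI) + ∫ κCI(x;X)(θC−θI) dx`,
with the kernel-weighted conductivity `κCI(x;X) = κCI · η₁(x−X)` (`η₁` the
amplitude-1 kernel of the active study).

**Heating terms.**  The heat deposited in `θC` by the concentration fluxes
is implemented in the conservative form

```
heat = c0 κ̄ (𝒢Φ : 𝒢q) + (c0/γ) q_f |𝒢Φ|²
```

evaluated on faces and averaged back to cells.  Together with the `F·M F`
term in `θP` this makes the closed system (bath off, noise off) conserve
`E = Ψ + c0 ∫Φq + C_PθP + C_IθI + C_C∫θC` exactly in space: the only energy
drift is the O(Δt²) time-integration error (measured ≈ 4×10⁻⁸ relative over
10³ steps).  Energy and entropy functionals and their exact gradients are in
`energetics.py`; `C_C` is a per-volume capacity (it multiplies `dV` in all
integrals).

**Ambient bath.**  The membrane–ambient conductivity `κ0` acts as a
relaxation `−(κ0/C_C)(θC − θ_bath)`, with `θ_bath` a uniform baseline for
the positioning/sensing studies and the sustained heating profile
`θ_m(x) = θ0(1 + c3 exp(−|x−x0|²/2σ3²))` for the escape study (an
"initial-condition-only" mode is available).  Closed-system runs set the
bath to `None`.

## Fluctuations

Each dissipative block is factorized as `K⁽ʲ⁾ = R⁽ʲ⁾R⁽ʲ⁾ᵀ` and sampled as
`h⁽ʲ⁾ = √(2 kB Δt) R⁽ʲ⁾ ξ⁽ʲ⁾` with independent standard normals per block:

| block | noise | notes |
|---|---|---|
| particle | `√(θP/γp) ξ` per axis | diffusivity `kB θP/γp` |
| P–I exchange | amplitude `√(κPI θP θI)`, weights `+1/C_P, −1/C_I` | no net energy noise: the weights cancel in `C_PθP + C_IθI` |
| I–C exchange | per cell, amplitude `√(κCI(x) θC θI)`, weights `1/(C_C√dV)` and `−√dV/C_I` | δV weights derived so drift = K·(discrete entropy gradient) |
| C–ambient | one-sided cell noise `√(κ0 θC θ_bath/dV)/C_C` | bath untracked |
| concentration | `𝒟(√(θC,f q_f/(γ c0 dV)) ξ_f)` | conserved; `q_f` is the **minimum** of the adjacent cells (see positivity) |
| conduction | `(1/C_C) 𝒟(√(κCC/dV) θC,f ξ_f)` | θC faces by arithmetic mean |

All factors cost O(N) per draw.  On small meshes the dense `K` is also
built independently from the defining formulas (dense divergence matrix and
diagonal face coefficients); `R Rᵀ = K` holds entrywise to 10⁻¹² of the
operator scale, and the empirical one-step increment covariance matches
`2 kB K Δt` with all z-scores below 5 at 10⁴ samples (the verification
module runs both checks).

## Discretization

Square periodic cells, centers at `(m+½)Δx`, fields stored row-major (y
then x), faces indexed by the cell on their negative side.  Forward
differences for `𝒢`, backward for `𝒟`, giving the exact adjoint pair
`𝒢 = −𝒟ᵀ` (asserted as dense matrices up to 32²).  Face coefficients for
drift terms (κ̄, θC, κCC, advected q) use arithmetic means of the adjacent
cells.  Gaussian kernels are truncated at `r_cut = 4σ0` with no
renormalization; the mass defect is `e⁻⁸ < 10⁻³` and the discrete midpoint
quadrature of the kernel is spectrally accurate, so an amplitude-1 kernel
integrates to 1 within 10⁻³ on the study meshes.  A 4-point immersed-
boundary (Peskin) kernel is available as an alternative; the Gaussian is
the default everywhere.  Particle positions are kept unwrapped (so MSDs are
meaningful); every particle–field displacement uses the minimum image.

## Time integration

Two-stage Euler–Heun: predictor with drift and noise at `Yⁿ`, corrector
averaging drift and noise coefficients at `Yⁿ` and the predictor state,
**reusing the same Wiener increments** — a Stratonovich integrator, so no
explicit `kB ∇·K` drift is added.  With a position-dependent scalar
mobility this scheme carries the Stratonovich spurious drift
`½ kB θ ∂M/∂X` (verified against an Ito–Euler reference); all three studies
use constant mobility, where the term vanishes.

**Stiff exchange.**  The printed protein–interface conductivities
(κPI ≈ 8×10⁶ with C_P ≈ 1 in the positioning/sensing parameter sets) give
an exchange rate ~10⁷, far beyond any explicit stability limit at the
studies' time steps.  In the variables (θP−θI, C_PθP+C_IθI) this block —
drift and noise together — is an exact Ornstein–Uhlenbeck process whose
noise cancels identically in the energy component, so it is advanced in
closed form as Strang halves around the Heun core.  The substep conserves
the exchanged energy to machine precision, reproduces the equilibrium
difference variance `kB θPθI (1/C_P + 1/C_I)` exactly, and reduces to the
standard scheme as `κPI Δt → 0`.

**Positivity.**  Temperatures must stay strictly positive and `q`
nonnegative; a violating step is rejected and retried as two halves (at
most 5 halvings, then a hard error).  Two refinements keep the conserved
multiplicative `√q` noise from dead-locking this rule near empty cells:
the noise face amplitude uses the minimum of the two adjacent cells (the
amplitude vanishes as the smaller cell empties, making overdrafts
self-limiting), and a negative band of 10× the single-step overdraft scale
`q* = 8 kB θ Δt/(γ c0 dV Δx²)` is accepted without clamping (so the mass
integral remains exact; ≈5×10⁻⁹ for the table-1 parameters).  Entropy
logarithms use `q_eff = max(q, 10⁻¹²)` and `0·ln 0 = 0`.

## Study configurations

Defaults are the three printed parameter sets (presets `table1`–`table3`,
spot-checked by tests).  Quantities the tables do not fix are package
choices:

* **Positioning** — blob `σ = 0.2` at `x1 = [1.5,1.5]`, protein at the
  origin, `k1 = 1.1`, `σ0 = 0.2`.  Outcome `y` = fraction of the
  minimum-image path from `x0` to `x1` covered (identical to the plain
  coordinate ratio on the short path).  Default sweep
  `κ̄ ∈ {1.2e-3, 0.12, 0.6}` at `γp = 13`; `T_end = 12` (the slow-signal
  transit completes by `t ≈ 5`); 8 replicates.
* **Sensing** — sensors in every cell column at mid-height, ζ width 0.1,
  filter `λ = 10⁴`, `β0 = 1/3` updated by the exact exponential
  integrator (unconditionally stable, exact DC gain).  The printed
  table-2 capacity `C_C = 40` is only consistent with the printed
  `Δt = 10⁻⁵` (stability) and with a detectable signal when read as a
  per-cell capacity; the scenario therefore uses `C_C/δV = 4×10³` in the
  per-volume convention.  Run length `T = 0.02` (~4 decay times of the
  initial profile) so that order-unity amplitudes remain resolvable while
  sub-percent amplitudes fall below the per-sensor replicate spread;
  reported statistic: second-half time average of the indicator, mean ± sd
  across 8 replicates, with detection defined as modulation > 3× the mean
  per-sensor sd.
* **Escape** — well width `σ0 = 0.2` (reusing the study-1 kernel width),
  heating width `σ3 = 0.3`, escape radius `r0 = 0.4`, sustained heating,
  50 replicates, censoring horizon `T_max = 60`.  The constant-temperature
  baseline escape time (~3.6×10² at the table values) is measured with the
  particle-only reduction over a long horizon — exact at `c3 = 0`, where
  the fields sit at uniform equilibrium and feed back only ~0.03%
  temperature fluctuations — and the full-model `c3 = 0` runs corroborate
  it by censoring at `T_max`.

The particle-only fast path (`simulate_particle`, `particle_escape_times`)
is the same two-stage update restricted to the position block at fixed
temperature; it backs the equilibrium checks, the barrier-height trend, and
the free-diffusion first-passage oracle.

## What the synthetic inputs do and do not emulate

Initial conditions (Gaussian blobs, sinusoidal profiles, heating spots,
band-limited random fields) are generated programmatically and seeded.
They reproduce the studies' geometry, not real membrane heterogeneity:
there is no lipid compositional disorder, no curvature, no crowding, and a
single mobile protein.  Passing tests therefore demonstrate the solver's
statistical-mechanical consistency (conservation laws, FDT, equilibrium
recovery, convergence) and the qualitative response of the three idealized
studies — not quantitative predictions for any specific biological
membrane.

## Numerical verification

* Conduction transfer operator: observed spatial order 1.99 (16²→64²,
  single mode, time step chosen so temporal error ≪ spatial error; the
  comparison is against the continuum solution, which is what makes order
  2 meaningful).
* Increment covariance: frozen 4×4 state with every block active, 10⁴
  one-step samples, z-scores vs `2 kB K Δt` bounded by 5 (the O(Δt)
  corrector bias is kept far below the Monte-Carlo error by `Δt = 10⁻⁵`
  at O(1) rates).
* Equilibrium: harmonic-well variance within 3 se of `kBθ/k`;
  free-diffusion MSD slope within 5% of `2kBθ/γp` at 10⁴ paths; closed
  deterministic system conserves energy to < 10⁻⁶ relative and produces
  entropy monotonically.
* Reproducibility: identical seeds give bit-identical trajectories;
  replicates are batch lanes of one seeded stream per condition.

## Known limitations

* No membrane shape undulations, curvature coupling, or hydrodynamic
  interaction between multiple particles (single-particle scalar mobility).
* The fluctuation blocks omit cross-couplings between the particle-position
  noise and the temperature noise; all stated contracts (symmetry, PSD,
  factorization, FDT covariance, conservation) hold for the implemented
  block structure.
* Explicit time stepping: parameter sets whose non-exchange rates exceed
  the stability limit need a smaller `Δt` (the integrator's rejection
  fallback handles transients, not sustained stiffness).
* The sensing detection threshold (3× replicate sd) and the escape
  censoring horizon are reporting conventions, not physical constants.
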