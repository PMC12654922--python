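# memselm

Stochastic Eulerian–Lagrangian simulation of protein drift–diffusion in flat
periodic membranes coupled to fluctuating concentration and temperature
fields.

## The problem

Membrane proteins move through environments that are *not* at equilibrium:
metabolic activity builds up local concentrations of signaling molecules,
heat sources impose temperature gradients, and at the ~10 nm / ~µs scales of
a membrane patch both concentration and temperature fluctuate spontaneously.
Point-particle Langevin models with a single bath temperature cannot
represent a protein that is hotter than its surroundings, heats up as it
diffuses into an illuminated region, or exchanges free energy with a
signaling field it is attracted to.

`memselm` simulates a hybrid discrete–continuum model for this regime.  The
state is

```
Y = [ X, q(x), θP, θI, θC(x) ]
```

a protein position `X`, the dimensionless distribution `q` of a signaling
species (concentration `c = c0·q`), and three temperatures: the protein's
own `θP`, the temperature `θI` of the interfacial lipid annulus around it,
and the membrane temperature field `θC`.  The coupled overdamped dynamics
are

* `dX/dt = M F_X + fluctuations`, with mobility `M = I/γp` and a force
  `F_X = −∇_X Ψ − c0 ∫ ∇_X Φ(x;X) q dx` combining a potential landscape with
  a kernel-mediated affinity for the signaling species;
* a conserved drift–diffusion equation for `q` with multiplicative
  (Dean–Kawasaki) √q flux noise;
* a heat equation for `θC` with conduction, kernel-weighted exchange with
  the interface, relaxation toward an ambient bath, and heating terms that
  reclaim exactly the mechanical free energy dissipated by the particle and
  the concentration flux;
* relaxation ODEs coupling `θP ↔ θI ↔ θC`.

The fluctuations are built from the dissipative structure itself: each
dissipative block `K⁽ʲ⁾` is factorized analytically as `K = R Rᵀ` and the
noise is `h_thm = √(2 kB Δt) R ξ`, so the fluctuation–dissipation relation
`Cov = 2 kB K Δt` holds by construction — including conserved noise for `q`
(exactly mass-free per draw) and energy-conserving exchange noise for the
temperature pairs.  Space is discretized with a periodic finite-volume mesh
whose gradient and divergence satisfy `𝒢 = −𝒟ᵀ` exactly; time stepping is a
two-stage Euler–Heun predictor–corrector that reuses the same Wiener
increments in both stages (a Stratonovich integrator), with the stiff
protein–interface exchange advanced by an exact closed-form substep.

Three configured studies ship with the package:

1. **Concentration positioning** — does the protein travel to a localized
   source of signaling molecules, or does the signal spread out and collect
   around the protein?  Controlled by the signal diffusivity and protein drag.
2. **Thermal gradient sensing** — a line of fixed kernel sensors filters a
   fluctuating temperature field through first-order reaction kinetics; at
   which profile amplitudes does the spatial signal survive the noise?
3. **Hot Brownian escape** — first-passage times of a particle out of a
   membrane energy well while a sustained heating spot raises its
   temperature.

## Worked example

```bash
python examples/positioning_by_concentration.py
```

prints (seed 7):

```
               mean       std
kappa_bar
0.0012     0.994547  0.002210
0.6000     0.049285  0.007763
```

`y` is the fraction of the distance from the protein's start to the
concentration source covered by the end of the run.  At the study value of
the signal diffusivity (1.2e-3) the protein reaches the source (`y ≈ 0.99`):
the blob stays put long enough to pull the protein in.  At a 500× larger
diffusivity the signal flattens and surrounds the protein before it can
move (`y ≈ 0.05`).  The example also prints the conversion to laboratory
units with the default reference scales (length 10 nm, time 1 µs, thermal
energy 4.1e-21 J): the patch is 20 nm wide and the run lasts 12 µs.

The other examples work the same way: `thermal_gradient_sensing.py` prints
the recovered spatial modulation against the replicate noise level per
profile amplitude, `hot_brownian_escape.py` prints mean escape times with
and without heating, and `validate_numerics.py` runs the verification
protocol (convergence order, covariance z-scores, equilibrium statistics).

A thin CLI wraps the same functions:

```bash
memselm run --scenario escape --seed 3 --out out/        # CSV summaries + config echo
memselm sweep --scenario positioning --values 1.2e-3,0.6 --seed 1 --out sweep/
memselm validate --suite all                             # JSON report, exit code
memselm fixtures --preset table1                         # resolved parameter set
```

## Layout

```
src/memselm/
  grid.py        periodic finite-volume mesh, mimetic operators, kernels
  params.py      physical constants and the three study presets
  energetics.py  energy/entropy functionals, potentials, protein force
  dynamics.py    drift assembly, K = R Rᵀ noise blocks, Euler–Heun stepper
  scenarios.py   the three studies, sensors, response filter
  validation.py  convergence / covariance / equilibrium verification
  config.py      YAML configs, presets, unit conversion, run outputs
  fixtures.py    seeded synthetic states for oracle tests
  cli.py         thin command-line front end
docs/methods.md  model, discretization and design notes
examples/        one narrative script per capability
```

See `docs/methods.md` for the model assumptions, parameter tables, the
noise factorizations, and the numerical design decisions (stiffness
treatment, positivity handling, study problem sizes).
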