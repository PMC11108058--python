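# Methods

`csfdrift` implements a reduced model of solute transport in the spinal
subarachnoid space (SAS): the thin annular, compliant canal of
cerebrospinal fluid (CSF) between the pia mater (around the spinal cord)
and the dura membrane.  The cardiac cycle drives an oscillatory CSF flow
whose cycle-average vanishes at leading order; drugs injected
intrathecally are dispersed by the much weaker *mean Lagrangian drift*
(steady streaming, Stokes drift and, when the drug density differs from
the CSF density, a concentration-dependent buoyancy drift).  A two-time
scale reduction separates the fast oscillation (period `2*pi` in the
dimensionless fast time `t`) from the slow drug evolution (slow time
`tau = eps^2 t`, with `eps ~ 0.02-0.04` the dimensionless stroke length),
so one unit of `tau` spans `1/(2 pi eps^2)` — hundreds — of cardiac
cycles that never have to be resolved individually.

## Model structure

Dimensionless coordinates: axial `x in [0, 1]` (entrance `x = 0`,
closed sacral end `x = 1`; gravity along `+x` for a sitting subject),
normalized transverse `eta = y/h in [0, 1]` (cord to dura), azimuthal
`s in [0, 1)` (periodic, `s = 0` posterior).  The canal geometry is the
width `hbar(x, s)`, cord perimeter `ell(x)` and compliance profile
`gamma(x)`; the governing groups are the Womersley number `alpha`, the
elastic wavenumber `k`, the reduced Schmidt number `sigma = eps^2 S`,
and the Richardson number `Ri` (positive = drug lighter than CSF).

1. **Oscillatory flow** (`oscillatory_flow`).  All leading-order fields
   are a single harmonic, e.g. `u0 = Re(i e^{it} U(x, eta, s))`.  The
   axial amplitude per transverse column obeys the Womersley channel
   problem `U + (i/(alpha^2 hbar^2)) U'' = dP'/dx` with no-slip walls,
   solved in closed form (cosh profile with complex decay rate
   `Lambda = alpha hbar sqrt(i)`); a finite-difference fallback solver
   cross-checks the transcription.  The axial pressure amplitude `P'(x)`
   satisfies a complex two-point boundary-value problem expressing the
   balance between section-integrated flux and the elastic wall motion
   `H' = gamma (1 + k^2 P')`, with `P'(0) = 0` (open entrance) and zero
   net flux at the closed end; the azimuthal pressure closes the
   azimuthal flux balance with an `s`-periodic (single-valued) pressure.
   The transverse amplitude `V` follows from continuity and satisfies
   the kinematic wall condition `V(1) = H'` (verified, second-order
   convergent).

2. **Mean flow** (`mean_flow`).  Cycle averages of products of harmonic
   signals reduce to conjugate products of amplitudes
   (`<Re(i e^{it}A) Re(i e^{it}B)> = Re(A conj B)/2`, and
   `Im(A conj B)/2` for mixed phase).  Three drift components:
   * *Steady streaming*: the order-`eps` mean Eulerian flow, driven by
     time-averaged convective acceleration, wall-motion correlations and
     the wall-modulated viscous stress; solved by the same quasi-steady
     lubrication structure (transverse Green solve + axial/azimuthal
     flux closures).
   * *Stokes drift*: the effective drift of the homogenized transport
     equation, obtained by averaging the oscillatory advection acting on
     the order-`eps` concentration response.  Its formula is the classic
     displacement-gradient average with the horizontal gradients taken at
     fixed physical transverse position (fixed `y`, not fixed `eta`)
     plus wall-correlation terms from the oscillating coordinate map.
     This distinction matters: the naive fixed-label particle drift has
     the same pointwise values only where the walls are parallel, and
     only the effective form makes the composed drift divergence-free
     with zero net axial flux section by section (closed width-averaged
     streamlines).
   * *Buoyancy drift*: closed-form transverse/azimuthal moments of the
     concentration (`calC`, `f_B` kernels), exactly linear in `Ri * c0`,
     vanishing identically for a transversely/azimuthally uniform solute
     (a uniform density offset is hydrostatic).  The concentration
     moments are evaluated with a segment rule exact for
     piecewise-linear `c0`, which preserves this gauge property to
     machine precision on any grid.

   Validation of the mean flow goes through two independent oracles kept
   in the test suite: a trajectory integrator in the reconstructed
   oscillatory field (validates the kinematic drift), and a
   finite-amplitude *time-domain* integration of the primitive unsteady
   lubrication system at `eps = 0.02` (semi-implicit viscous step, exact
   pressure projection) whose cycle-averaged velocity matches the
   harmonic steady streaming to about one percent, including the
   circulation direction in the eccentric annulus (fluid descends along
   the wide sector, returns along the narrow one).

3. **Transport** (`transport`).  The slow-time equation advects `c0`
   with the composed Lagrangian drift and diffuses it transversely with
   coefficient `1/(alpha^2 sigma hbar^2)`; the buoyancy drift depends on
   moments of `c0` itself, making the equation integro-differential.
   The drift is refreshed at every Runge-Kutta stage.

## Numerics

* Grids are uniform; `x` and `eta` include endpoints, `s` is periodic
  without a duplicated node.  Integrals use the trapezoidal rule (exact
  piecewise-linear product rules for the buoyancy moments); derivatives
  are second-order centred with one-sided closures at `x`/`eta` ends and
  periodic wrap in `s`.
* Transport uses upwind advection — minmod-limited linear (MUSCL)
  reconstruction on the axial/azimuthal faces by default,
  `upwind_order=1` for plain first-order — with explicit second-order
  (Heun) time stepping.  The default spatial form is conservative
  finite-volume on the metric-weighted density `ell hbar c0`, with the
  transverse face velocities re-derived per column from the discrete
  continuity of the axial/azimuthal fluxes (the transverse drift is
  defined by continuity in the first place).  Mass then changes only
  through the entrance face: the budget `retained + outflow = initial`
  closes to round-off, and the retained fraction `chi` is exactly
  non-increasing for a bolus.
* The time step is chosen from the actual per-cell update coefficients
  (sum of face CFL and diffusion rates) with a safety factor 0.4, so the
  explicit stage is positivity-preserving by construction; negative
  excursions beyond 1e-12 are clipped and logged (they are typically
  absent).
* Entrance condition: inflowing fluid carries zero concentration;
  outflow is free (pure upwind).  Walls and the closed end are no-flux.
* Alternative spatial forms are available for comparison:
  `scheme="advective"` (the plain non-conservative upwind form) and
  `scheme="consistent"` (a divergence-free advecting field with a strict
  maximum principle).  See "terminal region" below for why the default
  is the conservative form.

### Default resolution and problem sizes

The default grid is `Nx x Neta x Ns = 121 x 21 x 40`.  With the
limited second-order reconstruction this resolves the model-canal
dispersion cases (`alpha = 3`, `k = 0.5`, `sigma = 0.4`, banded bolus of
width 0.2 at `x0 = 0.65`, integrated to `tau = 3`) to well under one
percentage point in the retained fraction — a grid-doubling study moves
`chi(3)` of the light-solute case from 0.098 (at 101 x 17 x 32) to
0.088 (at 151 x 25 x 48) with first differences shrinking fast — while
each case completes in a few minutes on one core with the numba fast
path.  The test suite uses coarser grids for unit and property tests and
reserves the default grid for the headline dispersion checks.

## The terminal region (known limitation)

The lubrication model does not impose impermeability pointwise at the
closed end: the buoyancy drift `u_B(x=1, eta, s)` is generally nonzero
(only its section integral vanishes).  A negatively buoyant (hyperbaric)
solute is therefore driven onto the closed end, where — with no axial
diffusion in the reduced equation — it accumulates into an ever-thinning
sheet: the concentration at the last cells grows roughly like the
inverse grid spacing while the retained mass stays perfectly finite.
This is a genuine feature of the reduced model (the comparison with
fully resolved simulations shows exactly this discrepancy confined to
the terminal region), not of the discretization; the conservative
scheme represents the sheet as a localized concentrated layer and keeps
every integral diagnostic (`chi`, `C0`) well behaved.  Left alone, the
sheet's concentration-proportional buoyancy drift would shrink the
stable time step without bound as the sheet sharpens.  Because the
asymptotic derivation assumes `Ri*c = O(1)`, concentrations far above
the injected maximum are outside the model's validity anyway, so the
bolus driver saturates the concentration *as seen by the buoyancy
functional only* at ten times the injected maximum — far above every
resolved value.  The retained fraction is unchanged to four digits by
this cap (the sheet's mass and every transport flux are untouched); it
only tames the meaningless internal stirring of the unresolved layer.  The advective
form instead caps the sheet by its maximum principle but silently loses
the corresponding mass (about 20% by `tau = 3` in the heavy model-canal
case), which biases `chi` low; the "consistent" form deletes the
wall-converging flux altogether.  Retention diagnostics therefore use
the conservative default.

## Azimuthal gauge of the buoyancy drift

The azimuthal component `w_B` is defined up to an `s`-uniform flux
constant per section, fixed either by the printed closed form (zero
constant) or by requiring a single-valued mean azimuthal pressure.  The
two gauges give bit-identical dispersion results on the model canals
(the constant vanishes there); the printed form is the default and the
periodic-pressure gauge is available as an option.

## Synthetic geometries and what the tests show

All quantitative checks run on the two analytic model canals —
`hbar = 1 - 0.5 cos(2 pi s)` (constant eccentricity) and
`hbar = 1 - 0.5 cos(2 pi s) cos(2 pi x)` (variable eccentricity, a
cartoon of the cord's anterior/posterior excursions along the spine) —
with `ell = gamma = 1`.  These canals reproduce the mechanisms
(streaming cells, buoyancy-driven ascent/descent, recirculation
barriers) but not the anatomy: real canals have varying perimeter and
compliance, nerve roots and trabeculae, and respiratory forcing, none of
which are modelled.  Subject-specific geometries enter only as tabulated
`(hbar, ell, gamma)` arrays through the geometry reader, with the
compliance profile helper `gamma'(x) = 14.3 (0.8 + 0.3 tanh[4(x-0.2)])`
m/MPa available for the documented subject; passing the model-canal
tests therefore validates the solver machinery, not any clinical
prediction.

## Parameter defaults

| group | default | origin |
|-------|---------|--------|
| CSF density `rho` | 1.00059 g/cm3 | 37 C |
| kinematic viscosity `nu` | 0.7e-6 m2/s | CSF at body temperature |
| drug diffusivity `kappa` | 5.26e-10 m2/s | methotrexate (S ~ 1330) |
| cardiac frequency `omega` | 2 pi rad/s | 1 Hz heart rate |
| canal length `L` | 0.6 m | adult spine |
| width/perimeter `h_c`, `l_c` | 3.6 mm, 21.8 mm | subject measurements |
| stroke parameter `eps` | 0.02 | stroke length ~ 1 cm |
| `h_min` floor | 1e-3 | keeps `1/hbar^2` finite in tabulated geometries |
| CFL safety | 0.4 | explicit positivity margin |
| clip threshold | 1e-12 | negative-concentration bookkeeping |

Open design choices made here (and why): `k` is accepted as a direct
dimensionless input (`0.5` for the model canals, `0.73` for the
documented subject) because the compliance calibration that produces it
is upstream of this package; the mean compliance `gamma_c'` used to
nondimensionalize a tabulated profile is likewise a user input (its
averaging convention over an anatomical canal is not unique).
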