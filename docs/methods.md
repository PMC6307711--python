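# Methods

## The model

`chiralgrowth` simulates two cell strains competing at the expanding edge of
a compact aggregate (a microbial colony or a solid tumour cross-section) on
a rectangular lattice.  Each site is a deme of at most `N` cells; `n1` and
`n2` count the cells of the left- and right-labelled strains.  One timestep
consists of:

1. **Deterministic update.**  An auxiliary expectation
   `rho = n + (G + M) dt` is computed synchronously from the time-`t`
   fields.  `G = g n_a (1 - n/N)` is logistic growth on the shared carrying
   capacity.  `M` sums nearest-neighbour migration fluxes
   `n_a (1 - n_dest/N) (m0 + ms u_src + md u_dest + ml u_left + mb u_back +
   mr u_right)` where `u = n/N` and the coefficient labels are assigned
   *relative to the migration direction* (left = 90° counterclockwise).
   This makes the four lattice directions exactly equivalent while allowing
   a chiral bias: `ml != mr` biases motion at an angle to the local density
   gradient.  The exclusion factor `(1 - n_dest/N)` freezes the pattern
   behind the front, as in real colonies.
2. **Stochastic update.**  Two binomial rounds: total occupancy
   `n' ~ Binomial(N, (rho1 + rho2)/N)` (demographic fluctuations), then
   `n1' ~ Binomial(n', rho1/(rho1 + rho2))` (genetic drift).  `f = 0` and
   `f = 1` are absorbing.

In the continuum limit the model becomes a reaction-diffusion equation with
density-dependent diffusivity `D(n)`, straight advection `S(n)` and a
chiral advection `A(n) = 2 (ml - mr)(1 - n/N) dx^2/dt` multiplying the
90°-rotated density gradient (`chiralgrowth.continuum`).  Because `D`
depends on `ml + mr` and `A` on `ml - mr`, chirality can be tuned without
changing motility; the velocity-invariance test verifies this at the 1%
level.  Note that only `D` and `A` carry the `(1 - n/N)` exclusion factor;
`S(N)` stays finite.

### Numerical/implementation choices

- Expectations are clamped per strain to `[0, N]` and the pair rescaled
  proportionally when `rho1 + rho2 > N`; clamping warns because it signals
  out-of-regime coefficients (the standard parameter sets never clamp).
- Only a moving window of rows (`window_behind = 30` behind the front,
  `window_ahead = 30` ahead, advanced when the front comes within 5 rows of
  the leading edge) is updated; rows leaving the window freeze verbatim.
  Radial colonies use a moving annulus instead.  Growth and migration
  vanish in the saturated bulk and the empty exterior, so the window depth
  only controls how long a frozen site kept being resampled by drift; the
  desk-scale growth-penalty presets use `window_behind = 16` for speed.
- Performance: binomial variates are drawn only at sites whose outcome is
  random (`0 < rho1 + rho2 < N`, or both strains present), and the
  deterministic kernel skips the contiguous fully saturated row block at
  the bottom of the window — both exactly equivalent to the definition
  above.  All draws come from one `numpy` PCG64 generator in row-major
  order, so runs are reproducible bit-for-bit for a given seed.
- Mirror symmetry is exact: the `ml`/`mr` terms are grouped as a two-term
  sum, so reflecting `x` and swapping `ml` with `mr` commutes with the
  deterministic update at the level of floating-point bit patterns.
- Boundaries: periodic in `x`; no flux crosses the bottom (frozen interior)
  or top (empty exterior) lattice edges, so migration conserves cells
  exactly.

## Effective front theory

`chiralgrowth.theory` integrates the reduced description of the front: the
height `h(t, x)` obeys a chiral KPZ equation
`dh/dt = v0 + (v0/2)(dh/dx)^2 + Dh d2h/dx2 + alpha df/dx (+ noise)` and the
strain fraction a Burgers-type equation
`df/dt = Df d2f/dx2 + beta (f* - f) df/dx + v0 (dh/dx)(df/dx) (+ noise)`,
with multiplicative drift noise of amplitude `sigma_f sqrt(f(1-f))`.
`alpha, beta >= 0` scale with the difference of the strain chiralities and
`f* = chi1/(chi1 - chi2)` is the composite chirality (1/2 for equal and
opposite handedness).  Closed forms implemented alongside: the triangular
bulge `h - v0 t` of apex height `v0 alpha^2 t/(8 Dh^2)`, slope
`alpha/(2 Dh)` and half-width `v0 alpha t/(4 Dh)`; the apex velocity
`v0 (1 + alpha^2/(8 Dh^2))`; the flat-front boundary drift
`v_par = beta (1/2 - f*)`; and the piecewise-linear equilibrium fraction
(slope `beta Dh/(alpha v0)` inside the coexistence window
`|f* - 1/2| < alpha v0/(2 Dh beta)`).

Discretization: central differences for both diffusion terms and for the
`alpha df/dx` and `v0 (dh/dx)(df/dx)` couplings; first-order upwinding for
the Burgers advection with the side chosen by the sign of the local
advection speed `beta(f* - f) + v0 dh/dx`; and a Godunov (Hamilton-Jacobi)
upwinding of `(v0/2)(dh/dx)^2`.  The last choice matters: a bulge apex is a
slope corner that must advance at `v0 (1 + s^2/2)`, and plain central
differencing of the square gradient stalls it (we measured a ~20% flank
slope deficit at `alpha/Dh = 0.5, dx = 1`).  With the Godunov form the
residual deficit scales like `v0 s dx / Dh` and is ~2% at the
`alpha/Dh = 0.08` scale used for the quantitative comparisons.  Timesteps
are checked against `dt <= 0.25 dx^2/max(Dh, Df)` and
`dt <= 0.5 dx/|c|_max`; violations raise instead of silently corrupting.

**Sharp-boundary limit.**  In the noiseless coupled equations a *rising*
composition step (an in-flow boundary, the bulge-forming arrangement) is a
rarefaction wave of the Burgers flux and slowly spreads; the closed-form
bulge assumes boundaries pinned to near-zero width, which in the stochastic
model is done by genetic drift.  `integrate_front(..., freeze_f=True)`
integrates the height equation over a pinned composition profile and is
used for all quantitative comparisons with the closed forms.  Falling
(out-flow) steps are shocks and stay sharp on their own.

## Observables

- Front height `h(x)`: topmost `n >= N/2` crossing per column, linearly
  interpolated (a saturated front at row `k` reads `k + 1/2`); fraction
  `f(x)` averaged over a 10-row band behind the front.  The
  height threshold `N/2` and the band depth 10 are this package's
  operational definitions, and both are keyword arguments so sensitivity can be
  checked directly.
- Heterozygosity: per-column `mean(2 f (1-f))` from a profile, or per-site
  over the occupied active window (`window_heterozygosity`) for the
  intermixing diagnostics — the per-site variant is the one that
  distinguishes true cell-scale intermixing from column-averaged mixtures.
- Sector boundaries: `f = 1/2` crossings of the 5-column moving-average
  profile, labelled in-flow/out-flow from the flanking strains' handedness;
  tracked over time by periodic nearest-neighbour matching.
- Radial colonies: boundaries are extracted along rings of radius
  `r, r+1, ...`, linked by angular continuity, unwrapped, offset to zero at
  the innermost radius, averaged over the boundaries that survive the whole
  range, and fit to `theta = c0 + c1 ln r` (a Bernoulli spiral; `c1 > 0` =
  counterclockwise = left-handed).
- Boundary width: per-row sum over `x` of per-site `2 f (1 - f)`, averaged
  over a row window of the frozen pattern.

## Scenarios and desk scale

`chiralgrowth.scenarios` registers the reference parameter sets of the bundled experiments (circular
sectoring colony; patch invasion; opposite-chirality coexistence;
growth-penalty competitions; bulge formation; equilibrium-fraction scans;
intermixing transition; velocity checks) with the caption lattice sizes as
defaults, plus `--scaled` desk-scale presets (linear dimensions divided by
~3-5, replicates >= 4).  Scans derive each run's seed from (base seed,
axis value, replicate) only, so summary tables are invariant under
permutation of the value list.  Steady state is declared when the
trailing-20% linear-fit slope of the mean fraction falls below 1e-5 per
step.

The test suite runs everything at desk scale; the sizes that matter are:

- Coexistence at 50:50: width 200, `N = 100`, 4200 steps, 2 replicates per
  initial fraction in {0.25, 0.5, 0.75}.
- Growth-penalty thresholds: width 96 (chiral vs non-chiral, `g = 0.01`,
  22 000 steps, penalty grid {0,1,2,3,4,5,7,9}%) and width 128 (opposite
  handedness, `g = 0.1`, 9000 steps); runs are classified by the
  time-averaged trailing fraction (excluded >= 0.95, extinct <= 0.02).
  At this scale single replicates carry visible drift noise; the
  exclusion/extinction thresholds are asserted at +-2 percentage points.
- Equilibrium-fraction law: reference width 300 and `N = 200` retained;
  three replicates per `f*` started at `f0 = 0.5`, 12 000 steps each, with
  equilibria taken as trailing-half time averages (equilibration probes
  from `f0 = 0.25` and `0.75` converge to the same values).  The
  resampling-band depth mildly modulates the result: a shallower band
  (`window_behind = 16`) weakens the effective genetic drift, widens
  strain boundaries and flattens the fitted f̄_eq slope from ~1.4 towards
  ~1.2 at this lattice size — a real sensitivity of drift-dependent
  quantities to the band depth, worth keeping in mind when comparing
  absolute slopes.
- Spirals: 300x300 lattice, seed radius 15 (the full 700x700/radius-30
  geometry divided by ~2.3).
- Intermixing: width 200, 7000 steps, `N` in {40, 160, 320} at chirality
  0.05, and chirality in {0.01, 0.03, 0.09} at `N = 200`.

What the synthetic scenarios emulate — and what they do not: demographic
noise, genetic drift, chiral density-dependent migration and frozen-pattern
growth are all present; cell shape, adhesion, nutrient fields, off-lattice
geometry and 3-D structure are not.  Passing tests therefore validate the
lattice/continuum theory chain, not any particular organism's microscopic
parameters; the ~2%/~7% growth-penalty thresholds are themselves model
quantities of this class of reaction-diffusion models.

## Known limitations

- The proportionality between (`alpha`, `beta`) and the microscopic
  migration coefficients is not derived; the package estimates
  `alpha/Dh` and `beta/v0` empirically from bulge slopes and boundary
  velocities; the reference values 0.080 and 0.068 for the weak-migration
  strain pair come out of exactly this procedure.
- Noise amplitudes of the front equations are free parameters.
- Near the exclusion transitions the equilibrium fraction deviates from
  linearity (critical-region physics is out of scope), and desk-scale
  lattices add drift noise to every stochastic comparison.
- The universality class of the intermixing transition is not analysed;
  the tests only establish the monotone trends across it.
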