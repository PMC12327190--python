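# Methods

This note documents the model, its parameters, the numerical methods, and the
design choices behind them, in the package's own terms.

## Model overview

The simulator couples three layers on an annual cycle:

1. **Growth season (90 days).** Guild biomasses follow ordinary differential
   equations. Producers grow logistically against a shared carrying capacity
   K; consumers and fish feed through a multispecies functional response with
   Hill exponent q and half-saturation density B0; consumption capacity and
   maintenance scale with the mass-specific metabolic rate
   x = x_coef·m_C^(−1/4) (1/day, m_C the carbon body mass in mg). A consumer
   j gains x_j·y_j·B_j·F_ji from resource i (F the functional-response
   fraction); the resource loses that flux divided by the assimilation
   efficiency e_ji. Fish grow deterministically along their von Bertalanffy
   curves within the season (one growth-year accrues over the 90 days; there
   is no growth off season), so their metabolic rates and catchabilities
   change with season day. Fishing removes biomass at rate
   (E/t_end)·S_norm(L), which delivers a season-end survival of e^(−E·S_norm)
   for an otherwise static guild; mature guilds allocate biomass at a daily
   rate ra into reproductive pools, which fishing depletes at the same
   per-biomass rate as the guild itself.
2. **Reproduction and ageing (autumn).** Pools across the age guilds of a
   species define the parent trait distribution; the inheritance kernel
   (below) produces the larvae trait distribution; total larvae biomass is
   u = 0.8 times the pooled reproductive biomass. Age guilds then shift by
   one year cell-by-cell, the oldest guild acting as a plus group.
3. **Off season.** Fish biomass decays by exp(−fm*·x·(365−t_end)) with
   fm* = fm/2, evaluated at the start-of-next-season length (the step runs
   after ageing). Non-fish guilds carry over unchanged.

## The inheritance kernel

Two focal species discretise (L∞, k) on a bounded rectangular grid (genotype
groups). For an ordered parent pair (t₁, t₂) the offspring kernel is
bivariate normal with mean (t₁+t₂)/2 and covariance Σ = Ω^{1/2} Λ Ω^{1/2},
Ω = Ω_G + Ω_A. The genotypic part Ω_G = c_V·diag((t₁−t₂)²/2) uses the
two-point sample variance of the pair — the only symmetric variance of two
values; the additive phenotypic part is Ω_A = diag(σ̃²_L∞, σ̃²_k); Λ carries
the trait correlation ρ. The larvae distribution is the mixture over all
pairs weighted P(t₁)P(t₂), discretised cell-by-cell with the bivariate
normal CDF. Each component is truncated to the grid and renormalised to its
own in-grid mass, so the spawned biomass is conserved exactly.

**Heritability** is H = V_G/V_P per trait, where V_P is the marginal variance
of the larvae distribution with the full kernel and V_G the same with
Ω_A = 0. Because both are computed after truncation, H can exceed one when
the parent distribution sits against a grid border: the wide phenotype
components are all pulled towards the grid centre, compressing the phenotype
mixture below the genotype mixture. The test suite contains an explicit
two-mode border construction demonstrating this.

### Numerical evaluation

A naive evaluation needs G² kernel discretisations per spawning event
(G = grid cells). The implementation is exact-by-algebra up to two controlled
approximations:

- Pairs are grouped by absolute trait separation (|ΔL∞|, |Δk|); all pairs in
  a group share one covariance, so a group reduces to a 2-D convolution of a
  midpoint-weight lattice with a single discretised kernel. Per-component
  in-grid masses are themselves a cross-correlation of the kernel with the
  cell-centre pattern, which keeps per-component renormalisation exact.
- `eps_pair` (default 1e-8) prunes pairs with joint probability below the
  threshold; the total-variation error is bounded by eps_pair·G. Groups whose
  cumulative weight is below 1e-6 of the total are also dropped.
- `merge_tol` (default 0.05) merges kernel groups whose standard deviations
  differ by less than the relative tolerance (representative: the geometric
  mean of the bin ends). Measured total-variation error of the default
  settings against the exact double sum is ~1e-3 to 3e-3 on realistic
  distributions.

With `eps_pair=0, merge_tol=0` the computation reproduces the literal double
sum to floating-point accuracy (direct convolution, no windowing); this exact
mode backs the oracle tests. Kernels are windowed at ±8 standard deviations
otherwise (tail error ~1e-15). The bivariate normal CDF is an own vectorised
Gauss-Legendre quadrature of the Drezner-Wesolowsky single-integral form
(6/12/20 nodes by |ρ|, ~1e-13 accuracy for |ρ| ≤ 0.925; scipy's scalar CDF as
fallback beyond), cross-checked against scipy in the tests.

## Bayesian growth model

Lengths at fractional age a_t are Lognormal(μ_t, σ) with
μ_t = ln(E[L_t]) − σ²/2, so the distribution's *mean* equals the von
Bertalanffy expectation E[L_t] = L∞ − (L∞−L0)e^(−k·a_t). Fractional age uses
a nominal June-1 birthday and a 365-day year (leap days ignored). Priors are
independent uniforms on (L∞, k, L0, σ); zero-width bounds pin a parameter
(e.g. a literature L0). Sampling uses `n_chains` independent affine-invariant
ensembles (emcee; 16 walkers each) with the chain structure preserved for
split-R̂ and effective-sample-size diagnostics (arviz). Defaults: 4 chains,
1000 warmup iterations, 4000 recorded draws per chain. Non-convergence is
flagged on the posterior object, never silently dropped. The sampler is an
implementation vehicle: any correct MCMC would do, and the recovery and
coverage tests check the result, not the algorithm.

## Gear selectivity

Selectivity over length is δ/(√(2π)σ)·exp(−(L−μ)²/2σ²). Catches are
aggregated into 1-cm classes [c, c+1) keyed by the integer floor; the curve
is evaluated at class midpoints c+0.5. Fitting minimises the sum of squared
residuals with Nelder-Mead from ≥5 starts seeded at the data moments (the
heaviest class → μ start, biomass-weighted SD → σ start) plus seeded jitter;
σ and δ are optimised on log scale to keep them positive. Downstream only
the normalised shape matters: per-length mortality is E·S(L)/S(μ), reading E
as the *peak* instantaneous fishing mortality. Reference curve parameters
used by the examples: gillnet (μ = 46.72 cm, σ = 3.44 cm) on the piscivore
and small-mesh trawl (μ = 12.21 cm, σ = 1.71 cm) on the planktivore.

## The toy food web

`atne.synthetic.toy_foodweb` is a reduced pelagic web with known structure:
one phytoplankton producer, a grazing zooplankton guild, a scarcer predatory
zooplankton / pelagic-invertebrate guild, a shoaling planktivore ("prey",
4 age guilds, mature at 2, trait grid [10, 20] cm × [0.45, 0.65]/yr) and a
piscivorous top predator ("pred", 6 age guilds, mature at 3, trait grid
[70, 90] cm × [0.10, 0.20]/yr). Planktivore age 0 feeds on the grazer guild;
older planktivores mostly on the predatory zooplankton (food-limited adults);
young piscivores on zooplankton; older piscivores shift onto the planktivore
age guilds. All rate constants (x_coef, y, fm, ra, link preferences, K = 300,
B0 = 30, q = 2, lengths at birth) are fixture constants calibrated once so
that the unfished system holds a persistent, near-stationary equilibrium —
with trait distributions equilibrated — within a 100-year burn-in, and
survives a century of fishing at E = 2/yr. Initial guild biomasses default to
the equilibrium profile (stored on the guilds), and the initial trait
distribution is a truncated normal centred on the species' point traits,
which are themselves set at the unfished trait equilibrium. The fixture is a
test-bed design, not an estimate of any real lake.

Three properties of the toy web matter for interpreting results. First,
because every consumption gain scales with the metabolic rate x while some
losses (predation, spawning inefficiency) do not, population renewal keeps a
directional selection pressure towards higher x — smaller L∞ and k —
wherever those trait-independent losses are large; the planktivore's unfished
trait distribution therefore equilibrates in the lower region of its grid,
held by the balance between selection and the inward mixing bias of the
truncated inheritance kernel. Second, the species' relatively large lengths
at birth (4 cm for the planktivore, 15 cm for the piscivore) shorten the
trait-insensitive early-life window; the selection gradient is then dominated
by the older, food-limited stages, which is what lets the trait distributions
equilibrate on the burn-in timescale at all. Third, fishing adds a
length-targeted loss on top of this, and the directional-selection
experiments measure its effect *relative to the unfished control*, not
against the grid centre.

## Scenario driver and experiment design

A scenario is a 100-year unfished burn-in followed by a 100-year fishing
phase (both configurable); both focal species share the peak mortality E.
Years are absolute, so runs can be continued from a saved state (the fished
phase and its control share one burn-in). The sensitivity suite enumerates
all level combinations of (E, c_V, σ̃_L∞, σ̃_k) for one varied species — 3
levels each, 81 combinations — with the other species at its medium values,
repeated per correlation level ρ ∈ {0, −0.35, −0.7}; per-run seeds derive
from the master seed and combination index (order-independent, resumable).
Default level tables: E ∈ {0.5, 1, 2}/yr; c_V ∈ {0.125, 0.25, 0.5};
σ̃_L∞ ∈ {1.5, 3, 6} cm and σ̃_k ∈ {0.015, 0.03, 0.06}/yr for the piscivore;
σ̃_L∞ ∈ {0.5, 1, 2} cm and σ̃_k ∈ {0.01, 0.02, 0.04}/yr for the planktivore.

Biomass-change reporting compares terminal-window means (default: last 20
years; the window is a reporting choice) between a fished run and its
unfished reference, per aggregate group (focal species, other groups,
zooplankton+invertebrates, phytoplankton).

## Numerical choices

- **ODE integration:** scipy `solve_ivp`, default explicit adaptive RK45 with
  rtol 1e-6 / atol 1e-12. The right-hand side is smooth and non-stiff at the
  calibrated parameters; the method is config-exposed (`ode_method`) so
  implicit methods remain available for small webs. Negative undershoots are
  clipped inside the RHS and at season end; guilds below the extinction
  threshold (1e-6 mg C) are zeroed at season end only — mid-season clamping
  would break the integrator's error control.
- **Problem sizes:** the full experiment uses a 40×40 trait grid per species
  (1600 genotype groups); unit tests use 3×3 to 15×15 grids, and the
  acceptance script runs its scenario at 20×20 over 50+50 years. These are
  the package's default study sizes; the per-axis split of the genotype-group
  total is a free choice.
- **Heritability tracking** during scenarios is recorded at a configurable
  interval (it is diagnostic output; the dynamics never consume it).
- **Degenerate inputs:** zero-variance kernels place offspring mass in the
  containing cell (split evenly across a shared edge); an all-zero
  reproductive pool yields zero larvae that year; a focal species reaching
  zero total biomass terminates the run with a labelled status and partial
  outputs.

## Limitations

- The synthetic generators emulate idealised sampling: lognormal length
  scatter with age-independent shape, Gaussian catch noise, no year/cohort
  effects, no gear mixtures. Passing tests demonstrate correctness of the
  machinery, not realism of any particular lake.
- The toy web is small (13 guilds); real lake parametrisations have many more
  guilds and links, and their quantitative equilibria and biomass responses
  will differ. Qualitative mechanisms (directional selection under
  size-selective removal, trophic cascades) are what the toy web exercises.
- Growth is density-independent; maturation age/size do not evolve; escape
  mortality behind trawls is not modelled.
- Heritability here is a property of the modelled larvae distribution, not a
  pedigree-based quantity; it mixes genotypic and phenotypic notions by
  construction and is not comparable 1:1 with empirical heritabilities.
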