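# Methods

`braggrass` models the feedback loop by which wave-exposed seagrass
meadows can self-organize into regular bands: wave-induced bed shear
stress raises seagrass mortality; seagrass builds bed elevation (the
organo-sedimentary "matte"), so mortality patterns become topography
patterns; and periodic topography Bragg-reflects the incoming surface
waves, which imprints a partially standing shear-stress pattern back onto
the meadow. When the reflected stress pattern reinforces the topography
that created it, a uniform meadow is unstable and bands emerge at half
the water wavelength — the Bragg condition.

## Model

### Hydrodynamics

Irrotational surface gravity waves in one horizontal dimension are
described by a velocity potential φ(x, z, t) (u = ∂ₓφ, w = ∂_zφ)
satisfying ∇²φ = 0 in the water column, the linearized Bernoulli and
kinematic conditions at z = 0, and a kinematic condition at the bed.
Seagrass density n(x, t) sets the local depth H = h − s·n, with h the
bare-bed depth and s the topography coefficient (metres of matte per unit
density).

Because matte relief (order 1 m) is small relative to depth, fields are
expanded into a uniform basic state and a leading-order perturbation.
The basic state is an analytic monochromatic wave of amplitude a and
wavenumber κ satisfying σ² = gκ tanh(κH₀) at the uniform vegetated depth
H₀ = h − s·n₀. The perturbation state (η₁, φ₁, n₁) obeys

- ∂ₜφₛ₁ = −g η₁ − γ(x) φₛ₁
- ∂ₜη₁ = wₛ(φₛ₁, w_b) − γ(x) η₁

where φₛ₁ is the surface potential, wₛ the surface vertical velocity, and
the bed forces the column through the small-ripple transfer of the bottom
condition to the flat level z = −H₀:

    w_b = s ∂ₜn₁ + ∂ₓ(s n₁ u₀b),

with u₀b the basic-state orbital velocity at the bed. The vertical
structure is solved exactly per Fourier mode on the flat strip (a
Dirichlet-to-Neumann map), which makes the Laplace solve algebraic and
spectrally accurate.

### Seagrass

Seagrass dynamics combine net mortality ω = ω_b + ω_c τ_b (with τ_b the
wave-period-averaged bed shear stress ½ρf_w U_b²), facilitation α n²,
competition −β n³ and lateral dispersion δ ∂ₓₓn. The perturbation
equation retains the saturating nonlinearities so that growth can
equilibrate; its forcing is the leading-order stress perturbation

    τ_b1 = 2 ρ f_w ⟨u₀b u₁b⟩,

a trailing-one-period mean accumulated in a ring buffer every
hydrodynamic step.

### Uniform equilibria

The spatially uniform balance 0 = −ω(τ_b0)n₀ + αn₀² − βn₀³ couples to
depth through τ_b0(H₀): a denser meadow sits in shallower water and
feels more stress. The vegetated root is found by damped fixed-point
iteration with a bracketed root-finding fallback near the transcritical
point, where the root depends on ω₀ like a square root and the damped map
can cycle. The bare state loses stability to homogeneous invasion below

    a* = (sinh(κ_h h)/σ) √(−2ω_b/(ρ f_w ω_c)),

the transcritical amplitude at which ω(a, n₀=0) changes sign.

## Default parameter set

All defaults live in `equilibria.default_seagrass_params()` /
`default_wave_parameters()` and `braggsim.SimConfig`:

| parameter | value | meaning |
| --- | --- | --- |
| T | 8 s | forcing wave period |
| h | 4 m | bare-bed depth (field depth range of banded patterns) |
| ω_b | −1 (bio unit)⁻¹ | background net growth without waves |
| α, β | 0, 2 | facilitation/competition (logistic-type default) |
| δ | 0.1 m² (bio unit)⁻¹ | lateral dispersion |
| s | √2 m/density | 1 m matte at the unforced density n₀ = 1/√2 |
| ω_c | 0.075933 (bio·Pa)⁻¹ | places a* at exactly 0.5 m |
| a | 0.475 m (0.95 a*) | forcing amplitude, inside the patterning window |
| ρ, f_w, g | 1025, 0.05, 9.81 | seawater density, friction factor, gravity |

The biological rates are scaled so the unforced meadow density is O(1);
only rate *ratios* and the products ω_c·τ_b matter for equilibria and
thresholds. The default α = 0 makes the vegetated branch meet the bare
state continuously at a* (transcritical topology, a single vegetated
branch); with α > 0 the largest root persists slightly beyond a* up to a
fold at ω₀ = α²/4β, which the `bifurcation_diagram` flags via
`veg_exists` rather than hiding.

Choosing h: the dimensionless strength of the reflection feedback scales
with the matte-to-depth ratio (through κ/sinh(2κH₀)) and with patch
length, while the local decay rate of perturbations does not. With the
1 m matte normalization, a 4 m bare depth and a 20-wavelength meadow
place the modulation instability clearly below a* (measured a_MI ≈
0.73 a*); in deep water (h ≈ 10 m) the same normalizations leave the
uniform meadow stable for all a < a*, so patterning requires shallow
sites — consistent with where banded meadows are actually observed.

## Numerics

- Uniform periodic grid, Fourier collocation; sponge layers of width 2λ
  at both ends with a quadratic damping ramp applied to η₁ and φₛ₁ force
  the perturbation field to ≈0 at the boundary, so periodicity emulates
  an open channel. γ_max = σ was tuned on a monochromatic-pulse test
  (returned amplitude ≈ 2×10⁻⁴ of incident; stronger damping reflects
  off the ramp itself, weaker leaks through).
- RK4 for the hydrodynamics at dt = T/128; interior default of 20
  forcing wavelengths at 64 nodes/λ (32 in the test suite); Heun (RK2)
  for the seagrass update each hydrodynamic step.
- Timescale bridging: biological rates are per biological time unit
  (bio_timescale = 4000 s of physical time each); the morphological
  acceleration factor M = 10³ multiplies the biological step seen by the
  integrator, so 25 wave periods advance biology by 50 units. The
  hydrodynamics always sees the *unaccelerated* bed velocity in the
  bottom condition: feeding the accelerated rate in lets the
  artificially fast bed do work on the wave field and pumps a spurious
  sideband instability (observed at dominant wavenumber ≈ 1.4κ before
  this separation was enforced).
- Initial condition: η₁ = φₛ₁ = 0; n₁ is seeded zero-mean Gaussian noise
  (rms 10⁻⁴ n₀) on the interior, zero in the sponges. Five spin-up
  periods of hydrodynamics-only integration fill the stress-averaging
  buffer before coupling.
- Degenerate inputs: the k = 0 mode uses the analytic limits of the
  vertical solve (wₛ = w_b, φ_b = φₛ − w_b H₀); n₁ is clipped at −n₀
  (total density nonnegative) with a warning if more than 10% of the
  interior clips; frozen-topography runs stop at dynamic equilibrium,
  defined as interior-envelope drift < 1% per period over 5 consecutive
  periods.

## Diagnostics

Pattern spectra are Hann-windowed FFTs of the detrended interior n₁;
the dominant-mode search excludes the lowest two bins where window
leakage dominates. Growth rates are r = ln(A(25T)/A(0))/25 per forcing
period at the bin nearest 2κ. The modulation-instability amplitude a_MI
is the first sign change of r over an amplitude grid, refined by
bisection (tolerance 1% of a*, each evaluation a full run). Reflection
coefficients follow the max-over-interior definition K_R = max|η₁|/a over
the final period's envelope; a scan freezes the simulated pattern and
re-runs hydrodynamics for a grid of forcing wavenumbers (the forcing
period following the dispersion relation at fixed H₀).

The frozen-topography engine was validated against the classical
resonant-interaction result for a finite sinusoidal patch,
K_R = tanh(Ω₀ l/c_g) with Ω₀ = σκD/(2 sinh 2κH₀): measured K_R agrees to
within 2% at patch steepnesses in the linear regime, and doubles when
either the patch length or the bar amplitude doubles.

## Synthetic data

No redistributable wave-reanalysis series or pattern surveys exist, so
the generators emulate them: peak periods are log-normal (median 6.5 s,
log-sd 0.2, putting the 99th percentile near 10.4 s — the western
Mediterranean regime); significant height follows Hs = 0.04·Tp² with
40% log-normal scatter, so the top-1% bed-stress events are long-period
high swells; pattern observations are placed at half the shoaled
wavelength with configurable relative noise, which encodes the
half-wavelength relation by construction. Passing the end-to-end
recovery test therefore demonstrates the *pipeline's* consistency
(selection, shoaling, envelope, comparison), not field confirmation; the
generators carry no storm clustering, seasonality or measurement error
structure of real series.

## Limitations

- The hydrodynamics is linearized; reflected energy is not removed from
  the incident wave, so very large patterns over-reflect. Analyses stay
  in the linear-onset regime (25 periods from small noise).
- The instability is convective and noise-sustained: patterns grow while
  migrating against the waves, and measured growth rates depend on patch
  length. Long-time saturation behaviour interacts with the sponges and
  is not a reliable observable; only onset-regime quantities are used.
- One horizontal dimension only: banded patterns, not hexagonal gap
  fields.
- No canopy drag or frictional wave damping; the bed stress acts on the
  biology but not back on the flow.
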