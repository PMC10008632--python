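# Methods

This note documents the models implemented in `smcluster`, the
assumptions behind them, the defaults and why they were chosen, the
numerical choices that matter, and what the synthetic-data tests do and
do not establish about real data.

## Physical models

### Hole opening in a contractile sheet

A hole nucleating in a multilayered SMC sheet is treated as brittle
fracture of a viscoelastic material in the elasticity-dominated regime.
Elastic recoil of the sheet scales as E·h·(R_c − a) (modulus E,
thickness h, cell size R_c, hole width a) and is resisted by
cell–substrate friction k·R_c²·da/dt. The force balance integrates to
exponential saturation a(t) = a_max[1 − exp(−C t)] with
C ~ E·h/(k·R_c²); 1/C is the stretching time visible at the start of
opening. Near the advancing edge the crack profile reduces to the
parabola y = A√x, with A ~ √(G/E) connecting the measurable profile to
the adhesion energy G. `fit_hole_width` estimates (a_max, C) by
multi-start nonlinear least squares; `fit_tip_parabola` uses the closed
form A = Σy√x/Σx; `derive_constants` applies k = E·h/(C·R_c²) and
G = A²E.

Assumptions: a(0) = 0 at nucleation (the fit re-anchors the time origin
at the last zero-width frame); the sheet behaves elastically over the
opening timescale; friction is uniform. The stepwise advance of real
holes (one cell length per phase) is not modeled — only the envelope.

### Cluster rounding (active dewetting)

A freshly detached cluster is modeled as a volume-conserving prolate
spheroid with semi-axes a (long) and c, anisotropy ε = (c−a)/(c+a) ≤ 0
and mean radius r = (2a+c)/3. Shape change is driven by effective
surface tension γ and dissipated by tissue viscosity η through the
power balance γ·dS/dt = −η∫∇u:∇u dV. Near the sphere this linearizes to
dε/dt = −(15/56)(γ/η)ε/r, i.e. ln(ε/ε₀) is linear in ∫dt/r with slope
−(15/56)(γ/η). `fit_rounding` regresses per cluster and pools slopes by
inverse-variance weighting.

The 15/56 prefactor depends on the interior velocity-field solution; it
is taken as given for fitting. `dissipation_rate_check` evaluates both
sides of the power balance for any user-supplied incompressible
velocity ansatz (Gauss–Legendre quadrature over the spheroid,
finite-difference gradients, divergence check) and reports the
relaxation prefactor that ansatz implies. The naive affine
incompressible field gives a prefactor of order 1, not 15/56 — the
diagnostic is deliberately report-only, since the exact near-sphere
field is not reconstructed here.

### Cluster fusion (viscous sintering)

Two clusters in contact coalesce like viscous drops: neck radius
ρ²/R₀ = (γ/η)·t, with R₀ = √((A₁+A₂)/2π) from the initial projected
areas. The model holds between the viscoelastic time (minutes) and
geometric saturation; `fit_frenkel` therefore detects the plateau ρ∞
(median of the last quartile), restricts the fit to frames with
ρ < 0.9·ρ∞ (cutoff exposed as a flag), re-anchors t at first contact,
and fits a through-origin line to ρ²/R₀ versus t — the law has no
intercept. Multiple pairs are fitted independently and reported as
mean ± SD, mirroring how small-N fusion experiments are summarized.
The rendered plateau defaults to min(R₁, R₂): beyond that the "neck"
is no longer a neck between two identifiable lobes.

### Population dynamics

Total cluster count: dN/dt = p₁ − α(t)·p₂·N with α(t) = min(t/t_s, 1)
and N(0) = 0. p₁ (clusters/day) is the formation rate, p₂ (1/day) the
relative loss rate (mainly fusion), and t_s (day) the time needed for
clusters to become dense enough to interact; the ramp produces the
observed rise–peak–plateau shape with plateau p₁/p₂. Counts from
different seeding densities are onset-aligned before fitting (onset =
last all-zero day); on delay-structured data this reproduces a uniform
3-day shift for the lower densities and builds one master curve.
`fit_population` minimizes the unweighted SSE of an RK4 forward model
jointly over all aligned series, multi-starting from a coarse grid over
p₁ ∈ [1, 200], p₂ ∈ [0.1, 5], t_s ∈ [1, 20]. Developed and developing
clusters are summed; a two-compartment maturation model is out of
scope.

### Nematic order of stress fibers

Fibers are apolar, so order is computed on doubled angles:
Q = √(⟨cos2θ⟩² + ⟨sin2θ⟩²), 0 disordered, 1 perfectly aligned. The
finite-sample floor for uniform angles is E[Q] ≈ 0.886/√n. Angles can
be extracted from textured images by a per-window structure tensor:
Gaussian-derivative gradients (σ = 1 px) smoothed at σ = window/4, fiber
direction = minor eigenvector, coherence = normalized eigenvalue gap
used as a weight. Gaussian derivatives matter: small difference filters
pull oblique orientations toward the pixel axes by more than a degree.

### PIV

Standard coarse-to-fine windowed cross-correlation: the first pass uses
a window of final·2^(passes−1); each pass halves it, warping the second
frame by the previous field (integer shifts); the final pass is
32×32 px at 0.5 overlap with a three-point Gaussian subpixel peak fit.
Borders without a full window yield no vector. Outliers are vectors
exceeding their 3×3-neighbor mean (candidate excluded) by three times
the field-wide SD of valid magnitudes, iterated to convergence — a
purely neighborhood-local SD is inflated by the very outliers under
test whenever two land adjacent, which at a few percent outlier density
happens for a third of them. V_rms = √⟨|V|²⟩ over valid vectors;
px/frame converts to µm/h via the pixel size and frame interval.

## Defaults and study conditions

All defaults encode the conditions the pipeline is demonstrated at:

| parameter | default | meaning |
|---|---|---|
| pixel size | 0.65 µm/px | 32 px window = 20.8 µm |
| frame interval | 300 s (hole, speckle) / 1200 s (cluster scenarios) | fast vs slow acquisition cadence |
| a_max, C | 200 µm, 2×10⁻³ s⁻¹ | hole saturation; 1/C = 500 s |
| γ/η (rounding) | 10⁻⁸ m/s | capillary velocity of single-cluster rounding |
| γ/η (fusion) | 2.9×10⁻⁹ m/s | fusion is ECM-slowed, ~an order of magnitude below rounding |
| R₁ = R₂ | 100 µm | fusing pairs of ~200 µm diameter |
| p₁, p₂, t_s | 50 /day, 1.5 /day, 8 day | count dynamics; plateau 33.3 |
| ε₀, r₀ | −0.25, 100 µm | oblong initial cluster, 72 frames / 24 h |
| E, h, R_c | 2 kPa, 30 µm, 200 µm | sheet modulus; h = 3 layers × 10 µm (no direct measurement — k is an order-of-magnitude estimate) |
| noise | 5 µm width SD, 2 µm axis SD, 2 µm neck SD, Poisson counts | fixture choices; the source experiments do not quote measurement noise |

Orientation fixtures target Q = 0.18 / 0.51 / 0.87 for the
low/medium/high-density regimes by root-finding the von Mises
concentration on the Bessel ratio I₁(κ)/I₀(κ).

## Synthetic data: what it does and does not emulate

Generators emit the fitted kinetic laws plus measurement noise with a
single seeded RNG (named substreams per modality, so outputs are
bit-reproducible and adding a modality never shifts another's draws).
Masks are 8-bit 0/255 multi-page stacks, pixel centers at integer
coordinates, origin top-left. The neck is rendered as two discs plus a
tangent-capped bridge whose half-width is the ground-truth ρ; the exact
fillet is cosmetic.

Not emulated: hole nucleation from stochastic contractility (no cell
agents), cluster migration, arrested coalescence, spatially correlated
or heteroscedastic measurement noise, segmentation errors, uneven
illumination. Passing recovery tests therefore demonstrates that the
fits are unbiased and appropriately precise under idealized noise at
the stated conditions — not that segmentation of real phase-contrast
movies would achieve the same accuracy.

## Numerical choices

- Perimeter: arc length of the 0.5-level marching-squares contour of a
  lightly smoothed (σ = 1 px) mask. Pixel-edge counting overestimates
  perimeters of discs by ~27%, biasing circularity to ~0.79 and
  corrupting the 0.75 → 1 rounding readout; the subpixel contour is
  accurate to <0.5% for R ≥ 30 px.
- Circularity values in (1, 1.02] are clamped to 1 (digitization
  allowance); larger values flag a measurement failure.
- Tracking: nearest-centroid linking, gate = 3× the median per-frame
  displacement (5 px floor); ties resolved by smallest area change and
  logged. Minimum object area 100 µm².
- Rounding fit: frames with |ε| < 0.01 are noise-dominated and dropped;
  a sign flip in ε ends the usable segment (the decay has reached the
  noise floor); tracks with fewer than 5 usable frames are excluded
  with a warning. The regressor is the cumulative trapezoidal ∫dt/r
  with the per-frame r; `--assume-constant-r` switches to t/r̄ for the
  constant-radius reading of the law.
- Hole fit: multi-start over a decade grid of rates, bootstrap over
  time-point pairs (robust to heteroscedastic noise), explicit failure
  on monotone-decreasing series or series spanning less than one
  stretching time.
- Population ODE: fixed-step RK4; dt = 10⁻³ day for reference
  trajectories, 0.02 day inside the optimizer (discretization error
  ~10⁻⁶ relative, far below fit uncertainty). α's kink at t_s degrades
  RK4 locally to second order, which is why the reference step is kept
  small.
- Frenkel first contact: first frame with ρ above one pixel
  (0.65 µm at the default scale); origin at the preceding frame.
- Quadrature in the dissipation check: Gauss–Legendre in radius and
  polar cosine (n = 24 default), exact for the constant integrand of an
  affine field; divergence violations above 10⁻⁴ of the gradient scale
  reject the ansatz.
- PIV subpixel peak: three-point Gaussian; logs are guarded and a peak
  on the correlation border marks the vector invalid.

## Problem sizes

Recovery statistics quoted in the tests use 100 synthetic replicates
per scenario (60-point hole series; 7 tracks × 72 frames; 3 fusion
pairs × 48 frames; 9 count series × 15 days), 10⁵ angles for the
Bessel-ratio check, and 256² px speckle frames (225 vectors). These
sizes put every Monte-Carlo check within seconds while keeping the
estimator variance well below the tolerances being asserted.

## Known limitations

- The velocity-field ansatz reproducing the 15/56 prefactor is not
  re-derived; the dissipation check is diagnostic only.
- k is reproducible only to order of magnitude because the sheet
  thickness h is an assumption, not a measurement.
- The neck-width operationalization (minimal perpendicular chord on the
  central half of the centroid span) is one of several reasonable
  definitions; it agrees with the rendered ground truth to ~1 px but
  real necks with strongly asymmetric lobes may need the lobe centers
  supplied explicitly.
- `measure_hole` assumes one dominant enclosed hole per frame; merging
  or multiply-connected holes are reduced to the largest component.
- PIV does no window deformation beyond integer warping and no
  ensemble correlation; displacements beyond a quarter window of
  residual motion per pass are unreliable (the generator records a
  warning when asked to exceed this).
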