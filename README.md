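# smcluster

Analysis pipeline for the physics of smooth-muscle-cell (SMC) cluster
self-organization: cultured SMC sheets spontaneously tear, dewet, and
condense into three-dimensional clusters, and every step of that
sequence follows a simple kinetic law that this package generates,
measures, and fits.

## Who this is for

Groups doing time-lapse imaging of contractile cell monolayers
(smooth muscle, but the physics is generic to active cell sheets and
aggregates) who want to turn segmented mask movies into material-level
quantities — sheet friction, adhesion energy, and the tissue capillary
velocity γ/η — with a synthetic-data generator that makes every stage
testable without any raw movies.

## The models

Four kinetic laws cover the life of a cluster:

1. **Hole opening** (viscoelastic fracture of the sheet against
   substrate friction). The hole width saturates exponentially,

   a(t) = a_max [1 − exp(−C t)],  C ~ E·h / (k·R_c²),

   so the fit yields the stretching time 1/C and, given sheet modulus
   E, thickness h and cell size R_c, the cell–substrate friction
   coefficient k = E·h/(C·R_c²). Near the crack tip the edge profile is
   the parabola y = A√x with A ~ √(G/E) linking to adhesion energy G.

2. **Cluster rounding** (active dewetting). For a volume-conserving
   prolate spheroid near the sphere, anisotropy ε = (c−a)/(c+a) decays
   as

   ln(ε/ε₀) = −(15/56)·(γ/η)·∫dt/r,  r = (2a+c)/3,

   so the log-linear slope measures the capillary velocity γ/η.

3. **Cluster fusion** (Frenkel viscous sintering). The neck radius
   between coalescing clusters grows as ρ²/R₀ = (γ/η)·t with
   R₀ = √((A₁+A₂)/2π), until geometric saturation.

4. **Population dynamics**. The total cluster count obeys
   dN/dt = p₁ − min(t/t_s, 1)·p₂·N: formation at rate p₁, fusion-driven
   loss ramping up over the stabilization time t_s, plateau p₁/p₂.

Around these sit mask morphometry (area, perimeter via subpixel
contours, moment-based ellipse axes, circularity 4πA/P², neck and hole
width), the nematic order parameter Q = √(⟨cos2θ⟩² + ⟨sin2θ⟩²) of
stress-fiber angles with a structure-tensor extractor, and a three-pass
cross-correlation PIV (final 32×32 px window, 0.5 overlap, local
mean + 3 SD outlier filter, V_rms summary).

## Worked example

Everything is reachable from the `smcluster` CLI. The `suite` command
generates one default synthetic dataset per modality (with known ground
truth), runs every fit, and writes a summary table:

```sh
smcluster suite --seed 1 --out run/
```

`run/summary.csv` from this exact command:

| stage       | parameter            | recovered  | truth   |
|-------------|----------------------|------------|---------|
| hole        | a_max_um             | 198.36     | 200     |
| hole        | C_per_s              | 2.024e-3   | 2e-3    |
| rounding    | gamma_over_eta_m_s   | 9.357e-9   | 1e-8    |
| fusion      | gamma_over_eta_m_s   | 2.888e-9   | 2.9e-9  |
| population  | p1_per_day           | 51.42      | 50      |
| population  | p2_per_day           | 1.621      | 1.5     |
| population  | ts_day               | 8.076      | 8       |
| orientation | Q_LD / Q_MD / Q_HD   | 0.184 / 0.490 / 0.863 | 0.18 / 0.51 / 0.87 |
| piv         | u_px / v_px          | 3.153 / −1.763 | 3.2 / −1.7 |

Reading the table: the hole law was fitted on widths carrying 5 µm
measurement noise and still recovers the saturation width within 1%;
the rounding fit pools seven noisy cluster tracks into a capillary
velocity 6% from truth; the fusion and population fits land within a
few percent; the order parameter reproduces the low/medium/high-density
alignment levels; and PIV recovers a uniform subpixel shift to better
than 0.1 px.

Individual stages chain through files:

```sh
smcluster simulate hole --seed 3 --render --out hole/     # masks + CSV
smcluster measure hole --in hole/hole_masks.tif --px 0.65 --dt 300 --out hole.csv
smcluster fit hole --in hole.csv --boot 1000 --out fit.json
```

`fit.json` holds the parameters (a_max in µm, C in 1/s, the stretching
time 1/C in s), bootstrap standard errors, and residual diagnostics.
Library use mirrors the CLI: `gen_hole_series` → `fit_hole_width`,
`gen_rounding_track` → `fit_rounding`, and so on (see the module
docstrings).

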