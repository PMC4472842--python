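# Methods

## Model overview and assumptions

The simulator is a stochastic cellular automaton coupled to two continuum
fields on the same lattice. Its assumptions delimit what it can say:

- **Two time scales.** Nutrient diffusion equilibrates instantaneously
  relative to cell division, so each step solves a *steady-state*
  reaction–diffusion problem for the current biofilm shape. Transient
  diffusion, convection inside the boundary layer, and multiple nutrient
  species are out of scope.
- **Early growth only.** Occupancy never reverts (no death), and there is
  no shear, erosion, or motility. Biomass is monotone non-decreasing and
  stays 4-connected to the coverslip, because daughters are only ever
  placed edge-adjacent to existing biomass.
- **Reflective borders.** The coverslip (`z = 0`), the top (`z = d`), and
  the artificial sides are zero-flux for the nutrient field. For grids
  wider than ~100 cells the side-border treatment is immaterial: the
  package also implements periodic sides (`periodic_x=True`), and paired
  surveys show the mean-cell-depth distributions of the two conventions
  are statistically indistinguishable (this is a regression test).

## Parameters

| Symbol | Meaning | Units | Default | Explored range |
|---|---|---|---|---|
| `w, d` | grid width, depth | cells (≈ µm) | 128, 40 | fixed |
| `s` | inoculation separation | cells | 8 | 1–64 |
| `b` | boundary-layer thickness | cells | 7 | 1–16 |
| `r` | uptake–diffusion ratio `u₀/D` | 1/cell² | 0.5 | 0–5 |
| `p` | light penetration depth | cells | 2 | 0–30 |
| `I½` | light Monod parameter | – | 0.5 | 0–1 |
| `n½` | nutrient Monod parameter | – | 0.25 | 0–1 |
| `N` | placement block length | cells | 11 | fixed |
| `α` | distance-weight exponent | – | 2 | 0–3 |
| `β` | surface-energy weight | 1/cell | 1 | 0–3 |
| `A_max` | normalisation cutoff | – | 10¹² | fixed |

`b` maps inversely to flow velocity; `r` measures how strongly uptake
depletes nutrient relative to diffusive resupply (a Thiele-modulus-like
quantity); `p ≈ 2 µm` matches measured light penetration in late-stage
*R. palustris* biofilms. The defaults `b = 7`, `r = 0.5`, `α = 2`, `β = 1`,
`n½ = 0.25` are the configuration used for the package's survey figures;
`s = 8` (16 founders on a 128-cell coverslip) is our choice of a moderate
inoculation density — the source system gives no specific value, and over
the experimentally accessible range inoculation density showed no effect.

The diffusion constant and uptake rate never appear separately (only as
`r`), and the incident light intensity `I₀` is normalised to 1 (absorbed
into `I½`). Surface tension and `kT` are folded into `β`; per the printed
placement formula the distance factor is the reciprocal of the *squared*
Euclidean distance, with the ½ power folded into `α`.

## Numerical choices

- **Nutrient solve.** 5-point Laplacian at unit spacing; Dirichlet `n = 1`
  on bulk cells is eliminated from the system (bulk neighbours feed the
  right-hand side), so the sparse direct solve (SuperLU) only spans biomass
  + boundary-layer cells. `r = 0` and the empty biofilm short-circuit to
  `n ≡ 1` exactly. Round-off is clipped to `[0, 1]`, the discrete maximum
  principle's bounds. Against the 1D two-region closed form
  `n(z) = cosh(√r·z) / (cosh(√r·h) + b√r·sinh(√r·h))` the solver is within
  0.92% at the substratum for `h=4, r=0.25, b=7` at unit spacing. Under
  mesh refinement (scaling `h, b` by `f` and `r` by `1/f²`) the error
  decreases monotonically from `f = 2` onward; the unit-spacing grid
  benefits from partial cancellation of the half-cell interface offsets, so
  the convergence test starts at `f = 2`.
- **Boundary layer.** Euclidean distance transform between cell centres;
  media cells within distance `b` of biomass are boundary layer.
- **Light.** The column sum in the attenuation exponent includes the focal
  row, so a biomass cell shades itself; this follows the formula as printed.
- **Perimeter convention.** `ΔL = 4 − 2k` (k = biomass 4-neighbours),
  treating out-of-grid as media. This makes the local rule exactly equal to
  whole-grid perimeter recomputation, gives the exact symmetric placement
  probabilities (¼ for an isolated interior parent, ⅓ at the coverslip),
  and avoids spuriously attracting daughters to the artificial side walls
  (which would break reflective/periodic equivalence).
- **Division draw.** Strict inequality `P > V`, one uniform per grid cell
  per step in fixed array order, so the consumed random stream does not
  depend on biofilm shape.
- **Placement.** Dividing cells are processed in a uniformly random order
  and each daughter is visible to later placements within the same step
  (the connectivity guarantee then holds unconditionally). The `N × N`
  block is clipped at borders (wrapped when periodic). A run can be
  truncated at an exact biomass target mid-step so that surveys compare
  biofilms "grown to the same total mass" at exactly that mass.
- **Stopping.** Target biomass, a step ceiling, or a stall when
  `max P < 10⁻⁶` ("negligible" division probability; the threshold is a
  configurable parameter).
- **Determinism.** One `numpy` generator per run, seeded from the
  configuration; sweeps draw per-run seeds from their own seeded stream.
  Identical seeds reproduce trajectories, sweep tables, and feature tables
  bit-for-bit.

## Sweeps and their scale

`sweep()` samples parameters uniformly (optionally log-uniformly) from
configured ranges, runs each sample to a target biomass drawn uniformly as
a mean thickness in 0–40 µm (converted to cells via the grid width — the
simulation analogue of the COMSTAT biomass metric), and records parameters,
`1/n_s = b²r`, morphology metrics, and the coverage profile at 1 µm
spacing. The package's standard survey for trend statistics is **200
samples** over `b ∈ [3, 10]`, `r` log-uniform in `[0.02, 2]` (bracketing
the low/high-demand examples `r = 0.04` and `0.56` at `b = 7`), grown to
2000 cells; the light-compression comparison uses **20 paired runs** to 800
cells. These sizes give Spearman/sign-test significance with comfortable
margins while keeping a full survey around a minute on one CPU; the
hundreds of thousands of samples behind the original parameter-space maps
are configuration, not defaults.

## Synthetic image stacks

`imaging.synth_stack` renders three parametric phantoms — laminar film,
tapering columns, mushroom-capped pillars (a coverage peak 5–10 µm above
the base) — then applies depth-dependent exponential intensity decay and
additive Gaussian noise. This emulates the two properties of confocal
reflectance stacks the quantification path must cope with: a bright
foreground/background contrast and substantial signal attenuation with
depth. It does **not** model confocal optics (PSF, pinhole), speckle,
registration drift, or biological texture, so passing round-trip tests
demonstrates correctness of thresholding/coverage arithmetic and the
*rationale* for adaptive thresholds — not segmentation accuracy on real
stacks. With attenuation on, a sloped threshold schedule recovers phantom
coverage with ~20× lower error than the best constant threshold, which is
the adaptive threshold's purpose.

## Classifier path

Feature vectors normalise the coverage block to sum to 1 (making them
invariant to uniform scaling of a curve) and prefix one scalar: sample age
(experimental-style slices, 21 samples over 0–20 µm) or total biomass
(model output, samples over 2–20 µm; the first 2 µm are dropped because
coverslip-adjacent structure is least comparable between model and
images). The stated feature counts for the biomass variant are ambiguous
(19 vs 20); we sample 2–20 µm inclusive (biomass + 19 coverage values = 20
features) with `include_20um=False` available to drop the last sample.
Zero-coverage slices are excluded (normalisation undefined) and counted.

Because the original 324-stack experimental dataset is not deposited, the
end-to-end demonstrations train on rendered laminar (heterotrophic-like)
vs mushroom (photoheterotrophic-like) stacks from the synthetic generator,
passed through the full quantification path. The trained forest applied to
simulator sweeps assigns heterotrophic-like probabilities that fall with
`1/n_s` (rank correlation ≈ −0.7), mirroring the porosity trend; the
published OOB/accuracy figures for the experimental dataset are not
reproducible from synthetic data and are not targets of this package.

## Known limitations

- 2D only; quantitative parameter-to-experiment mapping is not attempted.
- The boundary layer is geometric (dilation), not hydrodynamic.
- The classifier trend on simulator output depends on synthetic training
  morphologies; absolute probabilities are not calibrated to experiment.
- Very scarce regimes (`b²r ≫ 10²`) take many steps per division and are
  slow at the default grid size.
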