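# biofilmsim

A two-dimensional hybrid discrete–continuum simulator of early bacterial
biofilm growth, with companion tools for quantifying confocal image stacks
and classifying biofilm morphologies. It targets the question of why
biofilms grown under different metabolic modes — heterotrophic (dark,
aerobic) versus photoheterotrophic (lit, anaerobic), as in
*Rhodopseudomonas palustris* — develop different architectures: dense flat
films, tapering pillars, or mushroom-capped columns.

## The model

The biofilm is a probabilistic cellular automaton on a `w × d` lattice of
1 µm cells (defaults 128 × 40), each biomass-filled (`c_xz = 1`) or
media-filled. Growth starts from founder cells spaced `s` apart on the
coverslip row `z = 0` and proceeds in discrete steps with two phases:

**1. Fields.** Nutrient enters by diffusion through a boundary layer of
thickness `b` (a circular dilation of the biomass). The equilibrium
concentration `n(x, z)`, relative to the bulk value, solves

    ∇²n = r c_xz n,   n = 1 in bulk media,  ∂n/∂z = 0 at the coverslip,

where `r = u₀/D` is the uptake–diffusion ratio. The discrete 5-point
Laplacian with mirrored (zero-flux) borders is assembled as a sparse linear
system and solved directly. For light-dependent growth, light enters at the
coverslip and attenuates through biomass (Beer–Lambert):

    I_xz = exp(−(1/p) Σ_{i≤z} c_xi),

with characteristic penetration depth `p` (≈ 2 µm for *R. palustris*).

**2. Division and placement.** A biomass cell divides with Monod
probability `K(n, n_half)` (times `K(I, I_half)` when light-dependent),
where `K(y, y½) = y/(y + y½)`. Each dividing cell places one daughter in
the `N × N` block around it (N = 11), on a media cell adjacent to biomass,
drawn with probability ∝ `R^α S^β`, where `R = 1/((x−x₀)² + (z−z₀)²)` is
the inverse squared distance to the parent and `S = exp(−ΔL)` penalises
surface-energy (perimeter) increase. Normalisations above `A_max = 10¹²`
(buried parents) are skipped. There is no cell death, shear, or motility —
the model covers early growth.

The dimensionless **nutrient scarcity** `n_s = 1/(b²r)` organises the
morphologies: abundant nutrient (large `n_s`) gives dense flat films, while
scarcity amplifies height fluctuations into porous columns. Light
limitation (small `p`, large `I_half`) compresses growth toward the
coverslip.

The imaging module segments 3D grayscale stacks with a depth-adaptive
threshold (anchors linearly interpolated across slices, compensating signal
attenuation), and reports COMSTAT-style biomass (mean thickness, µm) and
coverage-vs-depth profiles. The ML module turns coverage curves into
normalised feature vectors and trains random forests (1000 trees, Gini,
≤5 features/split) to distinguish heterotrophic-like from
photoheterotrophic-like morphology, with out-of-bag error estimates, naive
baselines, and a random-forest regression ranking which parameters drive
the classification.

## Worked example

```python
from biofilmsim.simulate import SimulationParams, run
from biofilmsim.metrics import convex_hull_density, mean_cell_depth

for label, r in (("low demand (r=0.04)", 0.04), ("high demand (r=0.56)", 0.56)):
    traj = run(SimulationParams(b=7.0, r=r, target_biomass=2000, seed=42))
    st = traj.final_state
    print(f"{label}: steps={st.step:3d}  biomass={st.biomass}  "
          f"hull density={convex_hull_density(st):.3f}  mean depth={mean_cell_depth(st):.2f} um")
```

prints

```
 low demand (r=0.04): steps= 11  biomass=2000  hull density=0.906  mean depth=7.34 um
high demand (r=0.56): steps= 30  biomass=2000  hull density=0.862  mean depth=7.48 um
```

Both runs grow to the same total mass (2000 cells, truncated exactly), but
the nutrient-scarce run (`1/n_s = b²r ≈ 27`) needs almost 3× as many steps
and produces a more porous, columnar biofilm: its convex-hull density (the
fraction of the biofilm's convex hull filled with biomass, an inverse proxy
for porosity) is distinctly lower. Over a (b, r) survey this trend is
strongly monotone (Spearman ρ ≈ −0.8 against `b²r`).

The same pipeline is available from the shell:

```
biofilmsim run --config cfg.yaml --seed 1 --out out/
biofilmsim sweep --ranges ranges.yaml --n 200 --seed 1 --out sweep.csv
biofilmsim quantify --tiff stack.tiff --anchors "0:0.5,20:0.1" --out coverage.csv
biofilmsim classify --train-csv train.csv --apply-csv sweep_features.csv --out scored.csv
```

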