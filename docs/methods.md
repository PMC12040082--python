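# Methods

## Scope and model

`forestacd` estimates plot-aggregate aboveground carbon density (ACD,
Mg C ha⁻¹) from a photogrammetric point cloud of a low-relief forest
site, and compares it against a field-inventory estimate. The carbon
model itself is deliberately borrowed, not fitted: five published
plot-aggregate allometries map a single stand metric, mean
top-of-canopy height (TCH, m), to ACD, and a configurable registry of
individual-tree allometries maps (DBH, H, WD) to per-tree aboveground
biomass. The package's contribution is the glue that makes the chain
testable: a reproducible CHM pipeline, seeded Monte Carlo error
propagation on both arms, and a synthetic scene generator with analytic
ground truth.

## Canopy height model

The cloud-to-CHM chain is: tile → isolated-point removal → ground
labelling → per-cell extreme thinning → rasterization → flat-DEM
normalization.

- **Noise filter.** A point is discarded when the 3×3×3 block of 1 m
  voxels centred on its own voxel holds ≤ 2 other points. Both
  parameters are exposed.
- **Ground labelling** is a simplified grid-minimum filter: the lowest
  point of each 2 m cell seeds a linear-interpolated candidate surface
  and points within 0.3 m of it are ground. This is *not* a port of any
  proprietary LiDAR ground filter; on the flat sites this pipeline
  targets, the flat-DEM step below supersedes most of its detail.
- **Thinning and surfaces.** The thinning grid defaults to 0.05 m, half
  the raster resolution (0.1 m). The DEM is built from *lowest*-thinned
  ground points with a min reducer and the DSM from *highest*-thinned
  points with a max reducer; that assignment is the physically coherent
  one (bare earth below, canopy surface above), and a `swap_surfaces`
  flag exists for comparison with workflow descriptions that state it
  the other way around. Unoccupied raster cells are filled from the
  nearest occupied cell within 0.5 m, else left nodata.
- **Flat DEM.** The single ground elevation is the 15th percentile
  (linear-interpolation convention, matching the percentile convention
  used everywhere else in the package) of the valid DEM cells. The
  accompanying histogram check verifies the chosen elevation lies
  within ±1 bin of the DEM histogram's modal bin — on a site with large
  exposed-ground fraction the modal elevation should be the floodplain
  surface. Bin width is Freedman–Diaconis floored at 0.25 m: the check
  exists to catch metre-scale vegetation contamination, and without the
  floor it trips on centimetre-scale measurement noise.
- **CHM.** DSM minus the flat ground elevation, negatives clamped to 0
  by default (clamping off is needed when diagnosing bias, see below).
  Plot statistics use cell centres inside (or on) the plot polygon.

**Known bias.** The p-th percentile of a noisy flat DEM sits below the
true ground by ≈ |Φ⁻¹(p/100)| × σ_DEM (≈ 1.04 σ_DEM at p = 15), so the
CHM of a bare scene carries a *positive* mean offset of the order of
the per-cell DEM noise SD, not of the standard error. Tests document
this: the zero-noise end-to-end CHM is identically zero, while at 5 cm
vertical noise the mean CHM offset is ~6 cm. For real data this bias is
far below the height-error scenarios propagated downstream.

## Drone arm (plot-aggregate Monte Carlo)

TCH measurement error is modelled as Gaussian with σ = 1.5 m
(optimistic, e.g. with ground control) and σ = 4 m (conservative),
1,000 draws each by default. Negative draws are truncated to zero by
default (`resample` and `none` are selectable); truncation keeps the
all-ACD-non-negative invariant and only matters for the large-σ
scenario at low mean TCH. One draw vector is shared across the five
equations within a scenario, keeping equation comparisons paired; the
summary table also reports the pooled SD recomputed with independent
per-equation draws, since sharing affects the pooled SD (slightly) but
not the pooled mean. Pooled summaries mix between-equation and Monte
Carlo variance by construction — that is the intended reading of the
pooled SD.

`reproduce_published_summary` runs exactly this on the two published
stand-level mean TCH inputs (plot 3.90 m, site 7.19 m) and tabulates
the all-equation and III–V-subset pooled means and SDs for both
scenarios. The small-error site III–V cell is known to come out ~9%
below the published value under every negative-draw rule; from the
printed inputs alone that cell appears to require information (e.g.
the site CHM's spatial height distribution) that a single mean TCH
does not carry.

## Field arm (ITC Monte Carlo)

Per simulation, each tree's DBH is perturbed with a 5% relative SD, its
height with a 3 m SD (typical clinometer uncertainty for small tropical
trees), and its wood density drawn from N(0.54, 0.11) g cm⁻³ — a
community-mean prior for Southeast Asian secondary forest used because
unidentifiable stems rule out database lookups. All perturbed values
are floored at 1% of nominal so power laws never receive non-positive
inputs. Plot ACD per simulation is the summed AGB (kg → Mg), divided by
plot area (0.25 ha default) and multiplied by carbon fraction 0.47,
applied per simulation (equivalent in the mean to applying it after
pooling). Each registry equation gets an independent, deterministic
seed substream; pooling k equations × n sims gives k·n samples.

Equations are parsed from a restricted expression grammar (DBH, H, WD,
numeric literals, `+ - * / ^`, `exp`, `ln`) validated on the Python
AST, so registries are plain data (YAML) rather than code. The shipped
default registry is a small set of *representative stand-in* forms;
any real analysis must supply the equations calibrated for its region.

## Synthetic scenes

The generator emulates the target site class: exactly flat ground
(true relief under a metre is treated as zero), 3–19 m trees with
paraboloid (default) or cone crowns of 1.5–3 m radius — single-apex
solids of revolution chosen to match the local-maxima detection
assumption — and DBH linked to height by the invertible rule
H = 3.0·DBH^0.5 so inventory-recovery tests have a known truth.
Rendering samples the *top* surface on a jittered grid (deterministic
counts under seed) at a chosen density, keeps bare-ground samples with
a configurable probability (photogrammetry reconstructs texture-poor
ground patchily), never samples ground under crowns (no canopy
penetration), and adds Gaussian vertical noise.

What this does **not** emulate: real SfM artefacts are spatially
correlated (doming, edge inflation, vegetation-density-dependent
ground visibility), crowns are neither solids of revolution nor
single-apex, and real relief is not exactly planar. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour
under idealized noise, not field accuracy of the method.

## Numerical choices

- Percentiles: linear interpolation everywhere.
- Rasters: north-up, origin at the min-x/min-y corner, NaN nodata in
  memory, ESRI ASCII grid on disk; cell membership by cell centre,
  boundary-inclusive.
- Tree-top ties: equal-height maxima resolved row-major, first wins,
  later ties within the search window suppressed.
- Crown growth: 4-connected, FIFO; apex cells are pre-claimed so a
  taller crown cannot swallow a neighbouring detected top; contested
  cells go to the taller top (deterministic).
- Sample SDs use ddof = 1; population variance appears only inside the
  law-of-total-variance identity test.
- All randomness flows through `numpy.random.default_rng` seeds;
  multi-stream consumers (scenarios, registry equations) derive
  substreams via `SeedSequence.spawn`, recorded in run metadata.

## Problem sizes

Default test and acceptance runs use scenes up to 100 m × 100 m at
50–60 points m⁻², 10,000 Monte Carlo draws per scenario for the
headline numbers (small enough to rerun casually, large enough that
Monte Carlo error is well inside the comparison tolerances), and 10⁵
draws where a test pins a distributional moment.

## Known limitations

- The flat-DEM approach is only valid on near-zero-relief sites; there
  is deliberately no terrain-following DEM mode.
- No CRS handling: all inputs must share one projected metric CRS.
- LAS/LAZ and GeoTIFF I/O are out of scope in this build; point clouds
  travel as XYZ text and rasters as ASCII grids, which the ecosystem's
  GIS tools read directly.
- Crown delineation quality on real, interlocking canopies depends
  strongly on the smoothing window and growth thresholds; defaults are
  tuned for the sparse, well-separated stands of the synthetic scenes.
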