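# pixelbaci

Pixel-level **Before-After-Control-Impact (BACI)** assessment of ecological
restoration from Landsat-like surface-reflectance time series.

Restoration projects (replanting, livestock exclusion) are rarely monitored
long enough to say whether they worked, and a naive before/after comparison
confounds the intervention with climate: a wet decade makes every hillside
greener. The BACI design separates the two by contrasting the temporal
change of each *impact* pixel against the change of *control* pixels that
looked the same before the intervention. This package implements that
design at 30 m pixel level for ecosystem services proxied by spectral
vegetation indices, end-to-end:

1. **Ecosystem-service models** — calibrate linear/quadratic regressions of
   field-plot indicators (stratified vegetation cover %, green biomass
   kg m⁻², spekboom cover %) on ten spectral indices (NDVI, SAVI, MSAVI,
   EVI, NPCRI, BSI, NBR, NBR2, NDMI, NDWI) and terrain, screened by
   VIF < 5, ranked by AIC, scored by repeated 5-fold cross-validation.
2. **Trajectory clustering** — ISODATA on pre-intervention multi-temporal
   index trajectories partitions the landscape into K (default 5)
   vegetation clusters: the control-matching strata.
3. **Scene selection** — drop scenes with > 5 % cloud in the control area;
   per analyzed year pick the "greenest" scene (max vegetation index or min
   bare-soil index over the study area).
4. **BACI engine** — per intervened pixel, draw n = 20 random controls from
   the same cluster and compute

   `contrast = (μCA − μCB) − (μIA − μIB)`

   where μ is the temporal mean (selected years) for the impact pixel and
   the temporal-and-spatial mean over the controls; the bare-soil index is
   sign-flipped so negative always means "the intervention helped". Each
   pixel also gets a relative contrast (% of its pre-intervention baseline)
   and a rank-test p-value against its own controls.
5. **Group statistics** — distance-thinned (≥ 60 m) pixel samples compared
   across interventions / clusters / aspect / soil parent material with
   Kruskal-Wallis + Games-Howell post-hoc, summarized by Hodges-Lehmann
   pseudo-medians, IQRs and compact letter displays; plus slope/elevation
   regressions on 10 % pixel samples.

A synthetic-landscape generator (`pixelbaci.synthgen`) produces
Landsat-like scenes with known cluster structure, shared interannual "year
effects", clouds, SLC-off stripes and a known additive intervention effect
δ, so the whole chain is testable without any satellite downloads:
`E[contrast] = −δ` exactly.

## Worked example

```python
import datetime as dt
from pixelbaci import (SynthConfig, generate_landscape, build_trajectories,
                       isodata_cluster, filter_clouds, build_period_spec,
                       run_baci)
from pixelbaci.rasterdata import SceneStack

cfg = SynthConfig(seed=42)                      # 100x100 thicket landscape
stack, terrain, sites, truth = generate_landscape(cfg)
thicket = sites.eligible_control | (sites.labels > 0)

pre = stack.between(dt.date(1989, 1, 1), dt.date(1990, 12, 31))
traj = build_trajectories(pre, "NBR", thicket)
clusters = isodata_cluster(traj, k=5, seed=1, grid_shape=stack.grid.shape)
print(f"clusters: {clusters.k}, converged after {clusters.n_iter} iterations")

clean = filter_clouds(stack, sites.eligible_control)
annual = SceneStack([s for s in clean.scenes if s.date.year > 2000], clean.grid)
spec = build_period_spec(1, 2012, annual, ["NBR"], area_mask=thicket)
print("before years:", spec.before_years, "after years:", spec.after_years)

result = run_baci(clean, spec, clusters, sites, "NBR", n_controls=20, seed=1)
t = result.table
print(f"analyzed pixels: {len(t)}")
print(f"mean BACI contrast: {t.contrast.mean():+.4f}  (true effect delta = 0.1)")
print(f"significant at p<0.1: {(t.p_value < 0.1).mean():.0%}")
```

prints

```
clusters: 5, converged after 1 iterations
before years: [2009, 2010, 2011] after years: [2017, 2018, 2019]
analyzed pixels: 1000
mean BACI contrast: -0.0987  (true effect delta = 0.1)
significant at p<0.1: 100%
```

The generator planted an additive post-intervention effect of +0.1 NBR on
the revegetation strip; the mean per-pixel contrast recovers −0.1 (negative
= impact improved more than its controls) despite shared year effects of
SD 0.05 — five times the pixel noise — because those cancel in the
contrast. The rank p-value against 20 controls bottoms out at 2/21 ≈ 0.095,
so "significant at p < 0.1" means a pixel's change exceeded all of its
controls'.

## Command line

A console script `pixelbaci` exposes the stages as subcommands —
`simulate`, `indices`, `calibrate`, `cluster`, `select-scenes`, `baci`,
`compare` — plus `run-all --config config.yaml`, which executes stages 1–5
from a single YAML file and writes a manifest with output hashes (two runs
with the same config and seeds are bit-identical). Scene rasters are
single-band GeoTIFFs named `<ISO-date>_<Band>.tif` (bands Blue, Green, Red,
NIR, SWIR1, SWIR2, optional `_mask`), sites are GeoJSON polygons with
`intervention` and `start_year` properties, field plots a CSV with header
`plot_id,x,y,strvc_pct,gb_kg_m2,sbc_pct`.

## Layout

```
src/pixelbaci/
  rasterdata.py   # grid contract, scene/terrain/site/plot I/O (GeoTIFF/GeoJSON/CSV)
  indices.py      # the ten spectral indices
  esmodels.py     # VIF screen, AIC ranking, repeated k-fold CV, prediction
  trajclust.py    # ISODATA trajectory clustering
  scenesel.py     # cloud rule, greenest-scene selection, period specs
  baci.py         # per-pixel contrast engine + p-values
  groupstats.py   # Hodges-Lehmann, Kruskal-Wallis/Games-Howell, thinning
  synthgen.py     # synthetic landscapes and field plots with known truth
  pipeline.py     # five-stage orchestration + manifest
  cli.py          # click CLI
docs/methods.md   # models, assumptions, parameter choices, limitations
```
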