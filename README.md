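# phenosync

Phenological synchrony between satellite-derived vegetation green-up and
the breeding dates of woodland birds.

In temperate deciduous woodland, great tits (*Parus major*) and blue tits
(*Cyanistes caeruleus*) rear their chicks on a short-lived spring flush of
caterpillars whose timing follows tree leaf-out. `phenosync` implements, as
a tested and reusable pipeline, an analysis that asks how well individual
birds track that timing when the vegetation signal is measured from space:

1. **EVI2 series** — per 240 m pixel and 8-day period, the mean of
   cloud-free looks of EVI2 = 2.5(NIR − Red)/(NIR + 2.4·Red + 1);
2. **green-up extraction** — a GCV-penalized cubic regression spline per
   pixel-year; green-up = argmax_t f′(t), the day of fastest greening;
3. **nestbox mapping** — bilinear, woodland-weighted interpolation of the
   pixel map to each nestbox;
4. **breeding records** — laying dates back-counted one egg per day from
   clutch observations, first broods only (≤ 30 d after the year's first
   clutch);
5. **mixed models** — laying ~ green-up split into between-year (annual
   mean ḡ_y) and within-year (g − ḡ_y) components, plus altitude, distance
   to the woodland edge and oak density within 75 m, with crossed random
   intercepts for year and nestbox (REML);
6. **synchrony landscape** — per pixel, the across-year Pearson r between
   mean laying date and pixel green-up, regressed on canopy/understory
   composition (weighted by breeding attempts) and compared between
   species;
7. **spatial structure** — Mantel correlograms of laying-date residuals
   and of pixel synchrony;
8. **cloud sensitivity** — annual synchrony regressed on mean cloudiness
   over all 91 windows of 3–15 8-day periods in the first 120 days of the
   year.

A synthetic-data module generates every input — landscape, habitat
compartments, cloud-thinned multispectral looks, nestboxes, breeding
records, caterpillar half-fall dates — from known ground truth, so each
stage is testable end to end without any satellite download. It is aimed at
spatial ecologists who want either the full pipeline or its pieces
(`fit_smooth_curve`/`extract_greenup_date`, `fit_mixed_lm`,
`mantel_correlogram`, `scan_windows`) as library functions.

## Worked example

Simulate a 8×8-pixel woodland with 400 nestboxes over 13 years and run the
whole analysis (about half a minute):

```python
from phenosync import SimulationConfig, PipelineConfig
from phenosync.pipeline import run_stage

cfg = PipelineConfig(outdir="demo_run", seed=42,
                     simulation=SimulationConfig(grid_rows=8, grid_cols=8,
                                                 n_years=13, n_nestboxes=400,
                                                 seed=42))
run_stage("all", cfg)
```

or equivalently `phenosync all --config demo.yaml` from the shell. The run
directory then holds, among others, `annual_correlations.json`:

```
"greenup_vs_halffall":        r = 0.909, p = 1.6e-05, n = 13
"greenup_vs_laying_blue_tit": r = 0.683, p = 0.010,   n = 13
```

— annual mean green-up tracks both the caterpillar half-fall date and mean
laying dates across the 13 simulated springs — and `model_fits.json` with
the great tit laying-date model (n = 1523 attempts):

```
greenup_within    0.146 ± 0.028   p = 1.1e-07
greenup_between   0.099 ± 0.099   p = 0.32
altitude          0.018 ± 0.008   p = 0.020
edge_distance     0.004 ± 0.001   p = 3.9e-06
oak_density_75m  -0.045 ± 0.012   p = 2.0e-04
variance components: year 4.62, nestbox 1.10
```

The within-year coefficient says birds at locally late-greening boxes laid
~0.15 d later per day of green-up delay — the generator's coupling
(0.02 d/d at zero oak, ×(1 + 25·oak) at the simulated oak densities)
averaged over boxes, recovered through the full satellite chain. The
habitat coefficients recover their generating values (0.028, 0.003,
−0.043). `synchrony_map_great_tit.csv` maps the per-pixel correlations
(here 35 included pixels, r from −0.46 to 0.66), `species_comparison.json`
holds the Welch test between species (blue tits more synchronized:
t = −3.78, p < 0.001), and `window_scan_great_tit.csv` ranks the 91
cloudiness windows against annual synchrony.

Every filtering step logs its counts (`--verbose`), every stage writes a
manifest with input checksums, and reruns with the same seed are
byte-identical.

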