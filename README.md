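# antdiv

Occurrence-based global biodiversity mapping for data-poor, hyper-diverse
taxa — the kind of analysis needed for insects, where most of what we know
comes from heterogeneous museum and literature records rather than expert
range maps.

`antdiv` implements the full inference chain from noisy occurrence records
to conservation-relevant maps:

1. **Record QC** — duplicate-locality pooling (coordinates rounded to four
   decimals), coordinate sanity flags, a decision tree that prioritizes
   original coordinates over geocodes and discards geocodes with precision
   radius > 100 km, and admin-centroid flagging.
2. **Range estimation** — triage by unique-locality count: < 3 localities →
   30-km buffered points; 3–4 → alpha hull (α = 15, buffered 30 km); ≥ 5 →
   a penalized presence-background suitability model fitted inside the
   buffered alpha hull after 10-km spatial thinning.
3. **Suitability modeling** — an L1-penalized log-linear (maximum-entropy
   style) model `p(x) ∝ exp(β·f(x))` contrasted against a bias-matched
   background sample; feature classes {L, LQ, H, LQH} × regularization
   multipliers {1…5} are tuned by cross-validation and selected
   sequentially (nonzero coefficients → Continuous Boyce Index > 0 →
   minimum 10-percentile omission rate → maximum validation AUC → fewest
   coefficients), with cloglog predictions on (0, 1).
4. **Diversity stacking** — richness `s_i = Σ_j w_ij` and damped rarity
   `r_i = Σ_j w_ij / (a_j + c)` with `c = 60,000 km²` (a circular range of
   radius ≈ 138 km), where `w_ij` is 1 for polygonal ranges or the cloglog
   suitability, and `a_j` is the spherical range area.
5. **Diversity centers** — the cells holding the top 10% of analysed area
   ranked by each metric, with the polar exclusion zone removed.
6. **Congruence & validation** — Spearman correlation and center-overlap
   against companion-taxon maps, upper-bound checks against community
   observations, block-maximum resolution sensitivity, and Chao2
   moving-window rarefaction (Hill q = 0) as an independent richness
   surface.
7. **Sampling-bias counterfactual** — a Random Forest of diversity on
   environment, realm, companion diversity and the sampling-density
   surface, tuned by 10 × 14 checkerboard spatial cross-validation
   (mtry 1–10); re-predicting with density := 1 everywhere yields the
   universal-high-sampling map and classifies each cell's center status
   as robust / drop / enter — the "enter" cells are the treasure map of
   predicted undiscovered diversity.
8. **Protection** — fraction of center area inside the dissolved
   protected-area layer.

Because the real record compilations and expert range maps are large,
license-restricted downloads, the package ships a first-class
**synthetic world** (`antdiv.synthetic_world`): seeded generators for
smooth environments, species with log-normal range areas and climate
niches, spatially biased collection with metadata noise, companion taxa
with controllable rank correlation, and protected-area polygons — all
with ground-truth labels so that every stage is testable end-to-end.

## Worked example

```python
from antdiv.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_species=40, resolution_arcmin=240.0,
                     lon_min=-120, lon_max=120, lat_min=-40, lat_max=40,
                     rf_trees=100, mtry_grid=(2, 4, 6), seed=7)
res = run_pipeline(cfg)

rep = res.qc_report
print(f"records: {rep.n_input} raw -> {rep.n_total_retained} retained "
      f"({rep.n_metadata_derived} metadata-derived + {rep.n_geocoded} geocoded)")
print(f"ranges: {res.manifest['ranges']['n_ranges']} species "
      f"({res.manifest['ranges']['n_sdm']} with suitability models)")
print(f"richness centers: {res.richness_centers.realized_area_fraction:.3f} "
      f"of analysed area")
print(f"robust rarity-center fraction under high sampling: "
      f"{res.robustness['rarity']['robust']:.2f}")
print(f"protected fraction of rarity centers: "
      f"{res.protection_coverage['rarity']:.2f}")
```

prints

```
records: 497 raw -> 485 retained (442 metadata-derived + 43 geocoded)
ranges: 36 species (2 with suitability models)
richness centers: 0.100 of analysed area
robust rarity-center fraction under high sampling: 0.97
protected fraction of rarity centers: 0.13
```

Reading: of 497 simulated collection events, 485 resolve to a usable
coordinate (the rest had an unfixable country conflict or only a coarse
geocode); 36 of the 40 simulated species were observed at all; the
detected richness centers realize almost exactly the requested 10% of
area; on this small world the high-sampling counterfactual leaves 97% of
the rarity-center area in place; and 13% of rarity-center area falls
inside the synthetic protected-area layer (which covers 15% of land).

The same run is available from the shell:

```bash
antdiv init-config cfg.yml
antdiv run --config cfg.yml --out out/      # all artifacts: .asc/.csv/.json/.geojson
antdiv centers out/richness.asc --config cfg.yml --out centers.asc
```

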