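# birdscape

Predicting urban bird diversity from remote-sensing vegetation metrics and
passive acoustic monitoring.

Urban planners need fast, inexpensive proxies for biodiversity. Two remote
sensing candidates are the Normalised Difference Vegetation Index
(NDVI = (NIR − Red)/(NIR + Red), a greenness measure bounded in [−1, 1])
and **vegetation volume** (canopy height from a normalised digital surface
model × pixel area, summed over vegetated pixels). On the ground-truth
side, week-long continuous sound recordings classified by a detector such
as BirdNET yield per-species detections at each monitoring site.
`birdscape` implements the full analysis chain that links the two:

1. **Acoustic diversity metrics.** Detections are filtered (confidence
   ≥ 0.8, per-site singletons removed, rare species reviewed) and
   summarised per species as the *vocal activity rate*

   VAR = (number of 15-minute periods with ≥ 1 detection) / (days recorded),

   capped by the 96 quarter-hour periods in a day. Site-level metrics are
   species richness *S*, total VAR, and a VAR-weighted Shannon diversity
   H = −Σ pᵢ ln pᵢ with pᵢ = VARᵢ / Σ VAR.
2. **Buffer vegetation statistics.** Mean NDVI and vegetation-volume
   density (m³/m²; log-transformed for modelling) in buffers of 25–800 m
   around each site.
3. **Scale optimisation & predictor comparison.** Linear models
   `metric ~ week + distance_to_centre + vegetation_b` for every buffer
   radius *b*; the buffer whose vegetation term most often attains the
   highest partial R² is selected, collinearity is screened at VIF < 5,
   and NDVI is compared with vegetation volume on model R². Residual
   spatial autocorrelation is checked with a permutation Moran's I test.
4. **Community ordination.** Non-metric multidimensional scaling
   (Kruskal stress-1, multiple starts) of the log(1+x) Bray–Curtis site ×
   species matrix, environmental-vector fitting with permutation tests,
   habitat-preference annotation, and a presence–absence/Jaccard
   cross-check via Procrustes (PROTEST) and Mantel tests.
5. **Predictive mapping.** An 80/20 train/test split, city-wide 100 m
   prediction grids averaged over the recording-week block, and evaluation
   by RMSE, MAE and standardized major axis (model II) regression.

A first-class synthetic-data module (`birdscape.syngen`) generates
spatially autocorrelated NDVI landscapes with a radial city-centre
gradient, canopy height coupled to greenness, and niche-structured species
whose occupancy and vocal activity follow the NDVI gradient — with the
ground truth retained, so the whole pipeline is testable end to end.

## Worked example

Simulate a 5 km city with 86 monitoring sites and run the full pipeline:

```bash
birdscape simulate --out demo/in --seed 42
birdscape run-all --indir demo/in --out demo/run
```

which prints the run summary:

```json
{
  "n_sites": 86,
  "best_buffer_m": 100.0,
  "best_predictor": "mean_ndvi",
  "nmds_stress": 0.14807659188070266,
  "rmse": {
    "richness": 2.053905426327455,
    "var_total": 35.34859147648096,
    "shannon": 0.08493054553352532
  }
}
```

Reading this: across all diversity metrics the vegetation term's partial R²
peaked most often at the 100 m buffer (the generating scale of the
simulation), mean NDVI out-fits log vegetation volume as a predictor, the
two-dimensional NMDS of the community matrix reaches stress 0.15 (a usable
ordination; < 0.2 is the usual rule of thumb), and the held-out root mean
square errors are small relative to the metric ranges (richness ~10–29,
total VAR ~150–470, Shannon ~1.9–3.3 in this simulation). `demo/run/`
contains the per-stage artefacts: site metrics, buffer table, model table,
predictor comparison, ordination report, prediction grids and the
evaluation report, plus a manifest with seeds and input checksums.

The same steps are available as library calls (`birdscape.acoustic`,
`.raster`, `.models`, `.ordination`, `.prediction`, `.pipeline`) and as
individual subcommands (`metrics`, `buffers`, `fit`, `ordinate`,
`predict`, `evaluate`, `select-sites`).

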