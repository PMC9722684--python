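# darkfleet

Estimate the number and length distribution of non-broadcasting ("dark")
vessels in a region by combining satellite-radar (SAR) ship detections with
AIS vessel tracks.

Many fishing vessels — pelagic longliners in particular — do not broadcast
AIS, so counts built from AIS alone miss an unknown fraction of the fleet.
Radar images detect vessels regardless of broadcasting, but two obstacles
stand between a detection list and a fleet estimate: deciding which
detections belong to broadcasting vessels whose last GPS position may be
minutes to hours old, and correcting for the vessels the radar itself
misses (small hulls) or mis-measures (noisy length estimates). `darkfleet`
implements an end-to-end pipeline for both, aimed at fisheries-monitoring
analysts and researchers working with scene-based SAR campaigns.

## Method

1. **Movement rasters.** For each vessel class, speed bin and signed time
   offset (6 × 6 × 36 = 1296 keys), an empirical raster of where vessels
   end up relative to a dead-reckoned extrapolation of their last position —
   a vessel-relative utilization distribution, with pixel width
   max(1, Δm)/1000 km on a 1000-pixel grid.
2. **Matching.** Each candidate vessel's before- and after-scene rasters
   are fused (weighted average when the closest ping is within 10 min of
   the image, cell-wise product otherwise) into a density p_v (vessels/km²)
   evaluated at each detection. Detections match vessels greedily while
   p_v·p_d > d_d·p_d + p_f — in practice a score threshold, default
   2.5×10⁻⁵ vessels/km². Near-ties within a factor of 100 are flagged,
   giving low/high match counts.
3. **Detectability and length error.** From matched vessels: a detection
   curve α(length) (median quantile regression below a 60 m knot, pooled
   plateau above) and a column-stochastic matrix L whose columns are
   lognormals fitted from the 1/3 and 2/3 quantile regressions of radar
   length on true length.
4. **Deconvolution.** The unmatched-detection histogram ℓ_o is inverted
   through ℓ_E = L(α ⊙ ℓ_A) by minimizing
   max|C_E − C_O| + (T_E − T_O)² — a Kolmogorov–Smirnov shape term plus a
   squared total-count term — over non-negative ℓ_A, with a split-sample
   bootstrap supplying a 90 % confidence interval.

A synthetic-world generator (correlated-random-walk fleets, configurable
dark fraction, Bernoulli detection in a length ramp, lognormal radar
lengths, false-detection field) provides ground truth for every stage, and
a coverage planner grids activity into 4°×4° cell-weeks and selects the
fewest scenes covering a target fraction of activity.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a 500-vessel world (20 % dark) with eight radar scenes, then run
the full pipeline (about five minutes on one CPU):

```python
import json
from darkfleet.simulate import SimConfig, make_recovery_case
from darkfleet.pipeline import RunConfig, run_full

make_recovery_case(SimConfig(n_vessels=500, seed=11), "bundle")
truth = json.load(open("bundle/truth.json"))

res = run_full(RunConfig(
    ais_csv="bundle/ais.csv", registry_csv="bundle/registry.csv",
    scenes_geojson="bundle/scenes.geojson", detections_csv="bundle/detections.csv",
    out_dir="run", bootstrap_n=300, seed=11,
))
c, e = res.manifest["counts"], res.manifest["estimate"]
print("true dark instances:", truth["n_dark_instances"])
print("matched:", c["matched"], "unmatched:", c["unmatched"])
print("dark total: %.1f" % e["dark_total"], "ci90: (%.1f, %.1f)" % tuple(e["ci90"]),
      "bootstrap mape: %.3f" % e["bootstrap_mape"])
```

Output:

```
true dark instances: 772
matched: 1368 unmatched: 422
dark total: 798.7 ci90: (643.3, 819.8) bootstrap mape: 0.105
```

Reading it: across eight scenes, 1368 radar detections matched to
broadcasting vessels and 422 did not; the unmatched detections, corrected
for length-dependent missed detections and radar length noise, imply about
799 dark vessel instances with a 90 % interval of (643, 820) — covering
the true 772 (a 3.5 % error). The split-sample bootstrap puts the mean
absolute percent error of the estimation process itself near 10 %, in
line with its design. At smaller sample sizes (~200 broadcasting vessels)
the fitted detection curve is noisier and point errors of 20–30 % occur;
the bootstrap interval is built to absorb exactly that fitting error.
The same run writes
`matches.csv`, `unmatched.csv`, `in_scene.csv`, `models.json`,
`estimate.json`, `histogram.csv` and a `manifest.json` with stage-by-stage
counts. The equivalent CLI is `darkfleet simulate` followed by
`darkfleet run-full`; `darkfleet build-rasters`, `darkfleet plan-coverage`
expose the individual stages.

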