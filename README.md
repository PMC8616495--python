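# aggremap

Quantitative analysis of anchorage-independent cancer-cell aggregation:

1. **synth** — synthetic bright-field time-lapse z-stack movies (with exact
   ground truth), gene-expression panels with planted parameter-coupled
   genes, and perturbagen signature libraries with planted
   concordant/discordant classes. Everything downstream is exercisable
   offline.
2. **imaging** — segmentation of multi-plane stacks: Laplacian-of-Gaussian
   focus fusion, morphological-opening background subtraction, Gaussian
   smoothing + saturation contrast stretch, Otsu thresholding, 8-connected
   component detection with an area cut (default 10,000 px ≈ 4160 µm² at
   0.645 µm/px), hole-excluded areas and outer-boundary circularity
   (4π·Area/Perimeter², capped at 1).
3. **kinetics** — per-well aggregation parameters from normalized-area
   curves: area-2h, trapezoidal AUC over an explicit window, end-point
   circularity; replicate summaries and two-sided Mann–Whitney comparisons.
4. **association** — regression-mode sparse PLS (exact per-component gene
   sparsity via calibrated soft-thresholding) linking the three parameters
   to expression; signed gene selections map to up/down query sets.
5. **connectivity** — weighted KS enrichment of up/down queries against a
   signature library, two-sided combined score (wtcs), stratum-normalized
   score (ncs), and signed-percentile tau in [−100, 100], summarized per
   perturbagen by median tau.

## CLI

```bash
aggremap simulate --out run/fixtures --seed 1            # synthetic fixtures
aggremap quantify --movie run/fixtures/movie --out run/q \
    --window 3.0 --preset synthetic                      # segmentation + parameters
aggremap associate --expression run/fixtures/expression.tsv \
    --params run/fixtures/parameters.csv --out run/a --keep-x 30
aggremap connect --library run/fixtures/library.tsv \
    --meta run/fixtures/library_meta.tsv --query run/a/query.gmt --out run/c
aggremap all --out run --seed 1 --window 3.0             # full chain
```

Stage parameters can live in a YAML file (`--config`, sections `synth`,
`imaging`, `association`, `connectivity`); explicit CLI flags override file
values. Every output directory gets a `run_config.json` with the resolved
configuration. The AUC window is always explicit — there is no silent
default.

Movies are one multi-page TIFF per frame (pages = focal planes) plus a
JSON sidecar (geometry, ground-truth footprint series). Expression
matrices and signature libraries are TSV; query gene sets are GMT.

## Notes

- All generators are pure functions of (parameters, seed); identical seeds
  reproduce movies bit-for-bit.
- `SegmentationConfig.for_synthetic()` is the documented preset for
  rendered movies (small objects need smaller smoothing/area cuts than the
  full-scale assay defaults).
- The perimeter estimator measures the marching-squares contour of the
  hole-filled object after a short circular moving-average smoothing;
  rasterized disks of radius 50–200 px score 0.98–1.0 and axis-aligned
  squares π/4 ± 0.02.
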