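# tregswitch

Analysis toolkit for studying phenotypic switching of CD4+ T cells into
FOXP3+ Treg-like cells. It bundles four analysis components plus the
synthetic-data generators needed to exercise them end to end without any
external data:

* **`tregswitch.treg_dynamics`** — three competing linear models of the
  non-Treg (X) / Treg (Y) population dynamics (heritable acquisition,
  enhanced proliferation, reversible plasticity), exact simulation via the
  matrix exponential, long-run regime classification
  (growing/saturating/declining), multi-start least-squares fitting on
  log1p counts, and AIC-based model selection. The plasticity model
  conserves the total population and has the analytic fixed-point Treg
  fraction `k_f*E / (k_f*E + k_r)`.
* **`tregswitch.fractal_spatial`** — Otsu/fixed segmentation, fixed-grid
  box counting, fractal dimension (log–log OLS slope), per-scale
  lacunarity `var/mean² + 1`, and Mann–Whitney group comparisons of image
  sets.
* **`tregswitch.cohort_stats`** — rectangular gating fractions, fold
  conversion between treated and control event tables, a two-sided
  Mann–Whitney U test (exact by enumeration for small tie-free samples,
  tie/continuity-corrected normal approximation otherwise), and the
  per-gene upregulated-cell-fraction statistic (threshold = mean of
  reference cells with detectable expression).
* **`tregswitch.synthetic_data`** — deterministic generators for flow-like
  event tables (log-normal FOXP3-low/high mixtures), noisy model
  trajectories, binary spatial patterns (uniform, clustered, Sierpinski
  carpet, solid, empty), and grouped negative-binomial single-cell counts
  with dropout and an ISG responder subpopulation.
* **`tregswitch.pipeline`** / **`tregswitch.cli`** — validated YAML
  configuration, per-stage seed fan-out, and a deterministic JSON run
  report.

## CLI

```sh
# simulate the plasticity model with observation noise
tregswitch simulate --model III --params params.yaml --noise-sd 0.05 --out traj.csv

# fit all three models and rank them by AIC
tregswitch fit --data traj.csv --model all --report fit.json

# generate spatial fixtures and compare two groups of masks
tregswitch synth image --pattern clustered --n-points 1500 --out mutant_0.png
tregswitch fractal --manifest slides.csv --measure both --out fractal.json

# gating statistics
tregswitch stats fold --treated t.csv --control c.csv
tregswitch stats isg --matrix counts.mtx --genes-file counts_genes.txt \
    --labels counts_cells.tsv --genes gene0000,gene0001

# full pipeline from a YAML config
tregswitch run --config config.yaml --seed 1 --out results/
```

`params.yaml` holds rate constants, e.g. `{k_f: 0.2, k_r: 0.05}`; a slide
manifest is a CSV with `path,group` columns and exactly two groups.

## File formats

* Flow events: CSV with one column per channel plus `condition`.
* Trajectories: CSV `time,x_obs,y_obs`.
* Masks: single-channel 8-bit PNG/TIFF (0 background, 255 foreground).
* Count matrices: MatrixMarket `.mtx` with `*_genes.txt` and
  `*_cells.tsv` sidecars.
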