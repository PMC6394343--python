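# hypersample

A sampling-design toolkit for field surveys driven by raster covariates
(terrain derivatives, sensor maps, categorical geology/soil layers). It
answers three practical questions around conditioned Latin hypercube
sampling (cLHS):

- **How many samples?** Sweep cLHS sizes, score each design by mean
  Kullback-Leibler (KL) divergence against the population, fit a negative
  exponential decay, and read off the size that captures 95% of the
  achievable improvement (`sample_size`).
- **Where else can I sample?** When a site is inaccessible, pick a
  replacement inside a metric buffer whose covariates are Mahalanobis-similar
  (negative-sigmoid similarity anchored at the buffer median, default
  threshold 0.975), with categorical layers enforced by exact match
  (`relocation`).
- **How do I account for existing samples?** Rank marginal quantile strata
  by the ratio of legacy-observation density to pixel density and allocate
  new sites to the most under-sampled strata (`ahels`); map per-pixel counts
  of covariate-similar legacy observations (`coobs`).

Core pieces: a covariate-stack data model with strict co-registration and
nodata-intersection masking (`covariates`), a seeded simulated-annealing
cLHS optimizer (`clhs`), binned KL / absolute-deviation metrics
(`divergence`), and a seeded synthetic landscape + legacy-design generator
(`synthetic`) so everything is testable offline.

## CLI

All commands are deterministic for a fixed `--seed` and write a JSON
run-manifest sidecar (`<out>.run.json`) with parameters and input digests.

```bash
# synthetic stack (GeoTIFFs + covariates.yml manifest)
hypersample simulate --nx 100 --ny 100 --ncov 5 --ncat 1 --seed 1 --out demo/

# draw a conditioned Latin hypercube sample
hypersample clhs --manifest demo/covariates.yml --size 50 --iterations 10000 \
    --seed 1 --out sites.csv

# per-covariate KL (or absdev) of a design against the population
hypersample evaluate --manifest demo/covariates.yml --sites sites.csv --bins 25

# sample-size sweep + decay fit + optimal size
hypersample optsize --manifest demo/covariates.yml --min 10 --max 500 --step 10 \
    --reps 10 --coverage 0.95 --seed 1 --out sweep.csv --plot decay.png

# relocate inaccessible sites within a 500 m buffer
hypersample relocate --manifest demo/covariates.yml --sites sites.csv \
    --radius 500 --threshold 0.975 --strategy random --seed 1 --out alt_sites.csv

# allocate new sites given legacy samples
hypersample ahels --manifest demo/covariates.yml --existing legacy.csv \
    --size 100 --seed 1 --out new_sites.csv

# per-pixel count-of-observations coverage map (+ crosstab of a design)
hypersample coobs --manifest demo/covariates.yml --existing legacy.csv \
    --threshold 0.975 --mode approximate --nsample 2000 --seed 1 \
    --out coobs.tif --crosstab-sites new_sites.csv
```

## Layout

```
src/hypersample/
  covariates.py   stack/design data model, readers & writers
  raster.py       GeoTIFF + ESRI ASCII grid I/O, grid geometry
  clhs.py         strata, objective, simulated-annealing sampler
  divergence.py   bin specs, KL & absolute-deviation metrics
  sample_size.py  size sweep, decay fit, coverage rule
  relocation.py   buffer zones, similarity, site replacement
  ahels.py        quantile matrix, density ratios, allocation
  coobs.py        magpd & coverage maps, crosstab
  distance.py     shared Mahalanobis machinery
  synthetic.py    seeded landscapes & legacy designs
  cli.py          click command group
```
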