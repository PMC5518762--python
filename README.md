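# hybridrange

Will climate change increase the overlap of climatically suitable ranges
between alien garden plants and their congeners in the resident flora —
and with it the opportunity for hybridization between them?

`hybridrange` implements the complete species-distribution-modelling
pipeline behind that question, and exercises it end to end on synthetic
climate grids and *virtual species* with known Gaussian niches, so that
every stage — occurrence cleaning, pseudo-absence design, model fitting,
ensemble consensus, range overlap, change statistics — is verifiable
offline against ground truth. It is written for invasion ecologists and
SDM methodologists who want a tested, reproducible reference
implementation of this workflow.

## The method in brief

For each species with cleaned presence records (one per 10′ grid cell,
water records removed), four SDMs are fitted on six bioclim predictors
(BIO4, BIO5, BIO6, BIO16, BIO17, BIO18):

* **regression family** — GLM and GAM against 10,000 random background
  absences;
* **machine-learning family** — BRT and RF against |presences|
  pseudo-absences drawn outside a 200 km exclusion radius, the draw
  repeated 10 times.

Case weights equalise the weighted sums of presences and absences
(w_p = 1, w_a = n_p/n_a). Each fit is scored by the true skill statistic

    TSS = sensitivity + specificity − 1

over three stratified 80/20 split-samples. Family projections are
TSS-weighted means, binarised at the maxTSS threshold, and a cell is
suitable in the final **consensus map** only where both families agree.
Range overlap of each within-genus (garden plant, congener) pair is the
TSS between their consensus maps and the count of jointly suitable cells;
per-garden-plant means are compared across warming scenarios via
ln(future/current) ratios in a linear mixed model with a genus random
intercept (REML), testing whether the mean log ratio differs from 0.

The synthetic world gives garden species thermal optima beyond the
regional warm edge (they are "native to warmer regions") and makes a
third of congeners cold-adapted, so warming should expand garden ranges
and shrink congener ranges — the directional truth the pipeline must
recover. See `docs/methods.md` for the full model description.

## Worked example

```python
from hybridrange import run_study

result = run_study(seed=1)   # ~5 min: 100x100 world, 24 species, 4 scenarios
print(result.tables["range_by_group"])
```

```
  scenario_id     group  mean_range_cells  sd_range_cells  n_species
0        BASE  congener          2476.500      496.753863         16
1        BASE    garden          1664.375      173.579078          8
2      MEDIUM  congener          2039.125      721.776778         16
3      MEDIUM    garden          2176.250      263.503185          8
4        MILD  congener          2301.750      627.758605         16
5        MILD    garden          1937.500      209.273574          8
6      SEVERE  congener          1381.000      816.989841         16
7      SEVERE    garden          2544.000      699.988571          8
```

Garden-plant ranges grow monotonically with warming severity (1664 →
1938 → 2176 → 2544 cells) while congener ranges shrink (2477 → 1381 under
the severe scenario) — opposite responses of the two species groups.
The mixed-model tests make the changes quantitative:

```python
print(result.tables["lmm_tests"].query("scenario_id == 'SEVERE'")
      [["metric", "group", "intercept", "p_value"]])
```

```
               metric     group  intercept   p_value
6  mean_overlap_cells    garden  -0.224155  0.476833
7          range_size    garden   0.391524  0.000095
8          range_size  congener  -0.736709  0.000000
```

Under severe warming, garden ranges increase significantly (mean log
ratio +0.39 ≈ +48%), congener ranges decrease significantly (−0.74 ≈
−52%), and the overlap between the groups does not increase (−0.22, not
significant) — despite more land being suitable to the potential
invaders, their spatial contact with resident congeners does not grow on
average. Because every virtual species' true range is known, the run also
validates itself: the consensus maps recover the truth ranges
(suitability ≥ 0.5) at a mean TSS of 0.77, all 24 species above 0.6.

The same analysis can be run as a narrative sequence of scripts:

```bash
python analysis/01_simulate_world.py --seed 1      # world + species + records
python analysis/02_fit_project_overlap.py --seed 1 # SDMs, consensus, overlaps
python analysis/03_report_change.py --plots        # headline tables + figures
```

Result tables (long-format CSV) land under `results/`, rasters and
figures under `scratch/`.

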