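# Methods

`hybridrange` asks a directional question from invasion ecology: when the
climate warms, does the geographic overlap between the climatically
suitable ranges of not-yet-naturalized alien garden plants and their
congeners in the resident flora grow or shrink? Growing overlap would mean
more spatial contact and therefore more opportunity for interspecific
hybridization — a known accelerant of plant invasions. The package
implements the full modelling chain and validates it end to end on
synthetic worlds where the right answer is known by construction.

## The modelling chain

**Occurrence cleaning.** Presence records are thinned to one per species
per 10′ grid cell, and records on water (masked) cells or outside the grid
are dropped as erroneous. Cells are half-open, `[west, east) × (south,
north]`, so boundary points have a unique owner; within a cell the first
record in input order wins.

**Pseudo-absences.** Presence-only data need artificial absences, and the
two model families get different designs:

* *regression* (GLM, GAM): 10,000 background points drawn uniformly over
  land cells, one jittered point per drawn cell;
* *machine learning* (BRT, RF): as many pseudo-absences as the species has
  cleaned occurrences, sampled uniformly from cells farther than 200 km
  (haversine, R = 6371 km) from every occurrence, with the whole draw
  repeated 10 times so no single background sample biases the final map.

Eligibility for the exclusion scheme is judged at cell centers against an
effective radius of 200 km *plus half the cell diagonal*, so the
within-cell jitter can never carry a point back inside the nominal radius;
the guarantee is strict, not approximate. Cells are drawn without
replacement when enough are eligible, with replacement otherwise (logged).

**Case weights.** In every training set the presence weight is 1 and the
pseudo-absence weight is `n_presence / n_absence`, making the weighted
sums of the two classes equal, so the large background sample does not
swamp the presences.

**Algorithms.** GLM is a logistic regression on standardized linear +
quadratic climate terms (quasi-unpenalised, C = 1e6); GAM is a binomial
spline GAM (6-df cubic B-splines per variable); BRT and RF are gradient
boosting and random forest classifiers at library defaults. Two numerical
choices matter: the GAM's IRLS is capped at 25 iterations because
presence/background data are often quasi-separable and the likelihood goes
flat long before formal convergence (predictions change < 1e-3 beyond
that), and GAM predictions clamp new climate values to the training range
because the B-spline basis is undefined beyond its outermost knots —
the standard "clamping" treatment of novel climates.

**Evaluation.** Each fit is scored by the true skill statistic,
TSS = sensitivity + specificity − 1, on three stratified 80/20
split-samples: fit on 80%, predict the held-out 20%, binarise at the
TSS-maximising threshold of the held-out predictions, record the TSS. The
threshold scan uses the sorted unique predicted probabilities as the
candidate set and returns the smallest candidate achieving the maximum —
finite, reproducible, and verified against a brute-force double loop.

**Ensembles and consensus.** Within each family the member projections
(2 regression members; 2 × 10 = 20 machine-learning members) are averaged
with weights equal to their mean split-sample TSS; members with
non-positive TSS are dropped with a warning. Each family's continuous
ensemble is binarised at the maxTSS threshold computed on the family's
pooled calibration rows, scored by the ensemble itself — the only
self-contained choice, since no held-out set exists at the ensemble level.
The threshold depends only on the training data, so it is computed once
per species and reused across scenarios. A cell counts as suitable in the
final consensus map only if *both* family binaries agree (logical AND) — a
deliberately conservative rule.

**Overlap.** For every within-genus, life-form-matched (garden plant,
congener) pair, overlap of the two consensus maps is scored as (i) the
TSS over unmasked land cells with the congener map as the reference
("observed") layer and (ii) the raw count of cells suitable to both. TSS
overlap is *not* symmetric in its arguments (the ad−bc numerator is, the
margins are not); the orientation is a configuration flag, and a
symmetrised mean is available for sensitivity runs. Pair metrics are
averaged per garden plant over its congeners, separately per scenario.

**Change statistics.** Each garden plant contributes ln(future/current) of
its mean overlap (and each species of its range size) per future scenario.
An intercept-only linear mixed model with a genus random intercept,
fitted by REML with a Wald test (statsmodels MixedLM), tests whether the
mean log ratio differs from zero; genera represented by several species
are thereby not over-counted. Natural logs; positive = increase. Species
with a zero metric in either scenario are excluded and counted (a zero
cannot enter a log ratio). If the REML fit is singular the result degrades
to the one-sample t-test and is flagged (`method="ttest_fallback"`).

## The synthetic world

Real inputs (WorldClim/Cordex rasters, GBIF records) are emulated so every
stage is verifiable offline:

* **Climate.** Six layers named after their bioclim analogues on a
  100 × 100 grid of 10′ cells: BIO5/BIO6 (max/min temperature) decline
  linearly with latitude (33→17 °C and 3→−14 °C), BIO4 (seasonality) grows
  with it, and BIO16/17/18 (precipitation) decline eastward, each plus
  smooth Gaussian-filtered noise. A contiguous land mass covers 70–95% of
  the grid; water cells carry no data everywhere.
* **Scenarios.** Warming futures are additive deltas of graded severity:
  +1/+2/+4 °C on both temperature layers (mild/medium/severe), with small
  seasonality and summer-drying shifts kept well below those layers'
  spatial standard deviation so temperature dominates the response — the
  only property the analysis uses is graded severity.
* **Virtual species.** Each species has a Gaussian product niche,
  s(x) = s_max·exp(−Σ (x_j−μ_j)²/2σ_j²), with breadths σ_j of 0.8–1.3
  landscape SDs. The default study has 4 genera × (2 garden plants + 4
  congeners) = 24 species, one life form per genus. Garden plants' thermal
  optima sit 0.5–1.5 SD *beyond* the regional warm edge — the
  truncated-niche signature of cultivated warm-region natives — so warming
  expands their suitable area; about a third of congeners are cold-adapted
  (the montane/alpine analogue) and shrink under warming, the rest sit
  mid-climate. Niches whose truth range (suitability ≥ 0.5) covers fewer
  than 50 land cells are redrawn, the analogue of a minimum-records rule;
  persistent failures progressively pull a garden species' overshoot back
  toward the warm edge so a modellable niche always exists, whatever the
  seed, without giving up the warm bias.
* **Occurrences.** 300 presence-only records per species: land cells drawn
  with probability proportional to true suitability, points jittered
  within the cell, duplicates allowed (a raw-GBIF-like extract).

What the generator deliberately does **not** emulate: spatial sampling
bias and detection error in occurrence databases, realized-vs-fundamental
niche mismatch (records are drawn from the truth niche itself), climate
change patterns beyond additive shifts, and any temporal dynamics
(dispersal lags, extinction debts). Passing tests therefore show that the
*pipeline* recovers known ranges and directions under clean sampling —
they do not certify performance on biased real-world occurrence data.

## Problem sizes and determinism

The default study (100 × 100 cells, 24 species, 300 occurrences, 10,000
background points, 10 ML pseudo-absence replicates, 3 splits, 4 scenarios)
runs in a few minutes on one core; every stage draws its randomness from
sub-seeds of one master seed, so a single integer reproduces the entire
analysis bit for bit. The mixed-model calibration checks use 200
simulation replicates of a 16-genera × 2-species design (μ = 0.3,
σ_genus = 0.1, σ_resid = 0.2).

## Design choices that were genuinely open

* Duplicate resolution keeps the first record in input order; only the
  water-body rule screens "erroneous" records.
* The regression family's 10,000 background points are drawn once per
  species; only the ML calibration is replicated 10 times.
* Final projections use models refit on 100% of the data, with the
  split-sample scores attached as weights (the alternative — projecting
  the split-calibrated models — discards 20% of the data for no gain
  here).
* TSS-overlap orientation defaults to congener-as-reference.
* The per-garden-plant *mean* overlap (not per-pair values) enters the
  mixed models, one response per garden plant and scenario.

## Known limitations

Grid geometry is geographic (plain lon/lat); no reprojection is offered.
The ~8,500-cell domain means the 10,000 background points essentially
tile the land surface, which is fine for the weighting contract but makes
the regression family's evaluation TSS conservative. With 4 genera the
genus-level variance of the mixed model is weakly identified in the
pipeline's own tables (the calibration simulations use 16 genera, as the
real study does). TSS-overlap of near-ubiquitous species is undefined
(empty margin) and such pairs are excluded with a report rather than
imputed.
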