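# Methods

`scalescape` implements a multi-spatial-scale analysis of colony-site
selection for colonial waterbirds: given presence points on a categorical
land-use raster, it asks *at which buffer radius* the surrounding land-use
composition best separates occupied from unoccupied locations (the scale of
effect), *which* land-use variable drives that separation, whether a few
influential samples distort the answer, and whether occupied neighbourhoods
are compositionally more diverse than unoccupied ones.  Because the original
study data (real colony coordinates and a national 30 m land-use raster) are
not redistributable, the package ships a synthetic-landscape generator with
a *planted*, recoverable preference, so every downstream claim can be tested
against a known ground truth.

## The synthetic landscape

`generate_landscape` draws one Gaussian random field per land-use class
(white noise smoothed at the correlation length `patchiness`, normalised to
unit variance) and assigns each cell the class whose field plus a per-class
offset is largest.  Offsets are calibrated iteratively so realised class
proportions match the requested `class_mix` (within a few tenths of a
percentage point on grids of 256×256 and larger).  Two properties matter:

- **Contiguity**: smoothing makes same-class cells spatially clustered, with
  patch diameter set by `patchiness`.
- **Exchangeable patch geometry**: because the class fields are independent,
  no two classes are systematically co-located.  A single-field
  quantile-band assignment (the obvious alternative) places classes with
  adjacent bands next to each other in space, which turns them into spatial
  proxies of one another; with such banding, variables neighbouring the
  focal class absorb much of its importance and variable-importance recovery
  fails.  The argmax-of-independent-fields mosaic avoids this by
  construction.

Default study conditions (chosen once, scaled ~1:20 from the original
China-wide protocol so all exclusion rules stay jointly feasible on a desk
-size domain): 512×512 cells at 100 m (51.2 km square), class mix
(cropland 0.20, forest 0.25, shrub 0.05, grassland 0.15, water 0.10,
barren 0.05, impervious 0.08, wetland 0.12), patchiness 1 500 m, border
band 5 km (analogue of the 100 km national-border rule), five town discs of
radius 1.5 km forced to impervious cover, a 1 000-point sighting pool, and a
1 km sighting-exclusion radius (analogue of the 5 km rule).

### The planted preference

`place_presences` proposes candidate sites uniformly over valid cells and
accepts each with probability `sigmoid(strength · z)`, where `z` is the
standardised **log availability** `log(f + 0.01)` of the focal class within
the focal radius (`f` = focal-class proportion in the disc, standardised by
its landscape-wide mean and SD).  Design rationale:

- *Monotone logistic weighting* keeps `strength` a single interpretable
  knob: 0 gives uniform placement, larger values concentrate presences in
  focal-rich neighbourhoods.
- *Log scale*: on a landscape where ~45–65 % of cells have no water within
  1 km, a logistic in the raw proportion still accepts zero-availability
  cells at a substantial rate (the raw proportion of an absent class is only
  ~0.4 SD below its mean), and nearly half the presences end up carrying no
  signal at all.  Log availability encodes the ecologically natural reading
  — some focal habitat within commuting distance is near-essential, more is
  increasingly preferred — and keeps the zero-availability acceptance rate
  a couple of percent at `strength = 5`.
- *Standardisation* makes `strength` a slope per SD of log availability,
  independent of how variable a particular landscape realisation happens to
  be.

Presences honour a minimum pairwise spacing (default 1 km).  The spacing
default matters: 100 presences at 2 km spacing need ≈350 km² by hexagonal
packing, which is comparable to the area of water-rich habitat on the
default landscape; at that setting the spacing constraint saturates the
preferred region and forces late presences into signal-free cells.  1 km
(≈90 km² packing demand) preserves the constraint's form — independent,
non-duplicated colonies — without competing with the preference.

When masks are supplied, presences are restricted to the same spatial
support as pseudoabsences (outside the border band and towns).  Without
this, the exclusion rules themselves become a class signal: buffer overhang
and town composition separate presences from pseudoabsences at *large*
radii, and the inferred scale of effect drifts to the largest buffers.  The
generator's contract is that the only systematic presence/absence difference
is the planted preference at its focal radius.

## Pseudoabsences

Candidates are rejection-sampled uniformly over valid cells and kept only if
they clear (a) the sighting-distance exclusion (exact, via a cell-binned
spatial index whose bin side equals the query distance, so a 3×3
neighbourhood scan is sufficient), (b) the border band, and (c) town discs.
Rejection sampling preserves conditional uniformity on the valid region,
which the tests verify by coarse-bin chi-square.  The pool defaults to 500
candidates from which 100 negatives are drawn without replacement;
`balanced_resample` produces repeated independent re-draws (the
"iterate-and-average" reading of resampling with replacement — within-draw
replacement would duplicate coordinates in a presence/absence design).

## Buffer features

For each point and each buffer (disc `[0, r)` or half-open ring
`[r1, r2)`), the area of each class is the count of cells whose *centre*
falls in the buffer times the cell area — standard zonal statistics on a
30–100 m grid, exact and cheap, and checked against an all-cells brute-force
oracle in the tests.  Half-open rings make ring + inner disc an *exact*
partition of the outer disc.  Buffers may overhang the raster edge; the
overhang contributes nothing and points whose largest buffer is more than
half off-raster are logged.  The Shannon diversity of a buffer is
`H = −Σ p_k ln p_k` over the class-area proportions (natural log; 0 for a
single-class buffer, ln 8 ≈ 2.079 at the 8-class maximum).

## Per-scale forests and the scale of effect

At each radius the model input is the 8 class areas of that buffer only.
`SubsampleForestClassifier` builds a random forest in which every tree
trains on a 70 % row subsample drawn *without* replacement, so each tree's
out-of-bag (OOB) set is exactly the stated 30 % (classic bootstrap leaves
~36.8 % out; `sampling="bootstrap"` restores it).  Forest OOB accuracy is
the majority vote over the trees for which each row was out-of-bag, scored
against the true labels; ties break toward the lower class index (stable).
`ScaleEnsembleClassifier` repeats this `n_models` times (library default
100 forests × 500 trees, the full protocol; the shipped configs use 20×100,
which reproduces the same scale ranking at a fraction of the cost) and
records the accuracy distribution.  The scale of effect is the radius with
the highest ensemble **mean** accuracy; ties break toward the smallest
radius and are reported.

Variable importance is Breiman permutation importance on the best
(max-accuracy) forest: per tree, each feature is shuffled among that tree's
OOB rows and the accuracy drop recorded, averaged over trees.  Two scales
are exposed: the raw mean-decrease-in-accuracy vector, and a clipped,
sum-to-one normalised version for ranking.  The normalised shares are only
meaningful when real signal exists — rescaling a near-zero vector amplifies
noise, so "no variable matters" must be judged on the raw scale (observed
null maxima ~0.02 accuracy; a genuinely driving variable sits an order of
magnitude higher).

## Deletion-based outlier screen

The screen deletes `k` rows (stratified so class balance moves by at most
one), refits the ensemble with the *same* model seed stream as the
baseline, and repeats over a grid of `k` with several replicates.  Two
facts shape the analysis:

- Uniform deletion keeps the outlier *fraction* constant in expectation, so
  the replicate-mean accuracy carries no outlier signal at any `k`; and
  shrinking the training set depresses all replicates as `k` grows.
- The signal lives in the **best replicate** per `k`: when deletable bad
  rows exist, the spread of "how many did this replicate remove" widens
  with `k`, so the best replicate's advantage over the replicate mean
  grows.

`trend_test` therefore regresses the per-`k` best-minus-mean **excess**
accuracy on `k` by OLS (options `best` and `mean` are retained; `mean` is a
useful flat control).  The overall best replicate's deleted set is the
flagged outlier group, and its advantage over the undeleted baseline
(`delta`) is compared with the baseline's between-model SD as a
selection-bias guard: on clean data the flagged "outliers" are a max over
noise and `delta` stays within ~2 SD.

Test sizing for the screen was chosen by a Monte-Carlo power analysis of
the trend statistic (simulating the hypergeometric removal process with
effect sizes measured from pilot fits: ≈1 percentage point of ensemble
accuracy per removed flip, residual replicate noise SD ≈0.005): a dense
deletion grid (1–49 step 2) with 8 replicates and small common-seeded inner
ensembles (4 forests × 30 trees — model-seed noise is shared across
replicates and cancels in within-`k` comparisons) detects 10 planted label
flips among 200 rows with ~90 % per-seed power, whereas a 5-point grid has
~40 %.  The delta guard uses the default 5-point × 5-replicate schedule
with 10 forests × 40 trees (fewer replicates limit max-selection bias; more
forests stabilise the SD band).

## Diversity tests and ordination

Per scale, presence and pseudoabsence Shannon values are compared by a
normality-gated two-sample test: Shapiro–Wilk at α = 0.05 per group; if
both pass, Welch's unequal-variance t test, else the Mann–Whitney U test
(U reported for the presence group; exact null for small tie-free samples,
normal approximation with tie and continuity correction otherwise).
Constant groups fall to the rank path with a warning.  All tests are
two-sided.

NMDS embeds the Bray–Curtis dissimilarities of row-normalised buffer
compositions in 2-D by non-metric MDS from multiple random starts,
reporting Kruskal stress-1; < 0.2 is the conventional rule of thumb for a
usable configuration, and stress is reported descriptively (no significance
test is attached to it).

## Determinism and seeds

Every operation is a pure function of its inputs and a seed.  The pipeline
derives one seed per stage by hashing (master seed, stage name), so adding
a stage never perturbs another stage's stream; repeated runs at the same
master seed produce byte-identical text outputs.

## Problem sizes

The shipped demo config uses a 256×256 grid, 60 presences, 300 candidates
and 20×100 ensembles over 9 radii (≈30 s end to end); the acceptance script
and recovery tests use the full 512×512 study conditions with 20×100
ensembles over all 13 radii (≈30 s per replicate world).  The paper-scale
100×500 ensembles are the library defaults and run unchanged, in minutes
per scale sweep.

## What passing tests do and do not show

The generator emulates composition (a categorical mosaic with tunable
patch size and mix), a single-scale habitat preference, and the sampling
constraints of a pseudoabsence design.  It does not emulate spatial
autocorrelation *between* presences beyond the spacing rule, observation
error in coordinates, class-boundary raster error, multi-scale or
multi-class preferences, or landscape gradients (e.g. coast-to-inland
trends).  Passing recovery tests therefore show the pipeline can find a
single planted scale and variable under clean conditions — a necessary
correctness property, not evidence about any particular real dataset.
Known limitations: the scale of effect is resolved only to the radius grid;
normalised importances of correlated compositional features spread credit
(areas in a buffer sum to ≈ the buffer area, so one class's abundance is
another's absence); and the outlier screen's flagged set is the best of a
random search, not an exhaustive influence analysis.
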