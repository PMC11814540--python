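# scalescape

Multi-spatial-scale analysis of colony-site selection for colonial
waterbirds (herons and their relatives), built around a fully synthetic,
ground-truthed test bed.

Colonially breeding waterbirds choose nesting sites in response to the
landscape around them, but *at what distance* the landscape matters — the
scale of effect — is itself an empirical question.  The standard study
design asks it like this: take presence points (colony sites) and
pseudoabsence points (random locations sampled under exclusion rules, since
true absences are unobservable), measure the area of each land-use class
(cropland, forest, shrub, grassland, water, barren, impervious, wetland)
inside circular buffers of many radii around every point, fit a separate
random-forest classifier ensemble at each radius, and let out-of-bag (OOB)
accuracy decide which radius carries the signal.  Permutation importance at
the winning radius names the driving variable; a deletion-based screen
checks whether a few influential samples distort the ranking; and per-scale
Shannon-diversity comparisons ask whether occupied neighbourhoods are more
compositionally diverse than unoccupied ones.

`scalescape` implements that entire pipeline, plus the piece a real study
cannot give you: a synthetic landscape generator that *plants* a known
preference (e.g. "water abundance within 1 km, logistic selection
strength 5") so scale recovery, importance recovery, outlier-screen power
and diversity-test power are all measurable against ground truth.

## The model in brief

- **Landscape**: categorical raster, one Gaussian random field per class,
  cell class = argmax of field + calibrated offset; patch size set by a
  correlation length, class proportions match a target mix.
- **Presences**: rejection-sampled with acceptance
  `sigmoid(strength · z)`, `z` = standardised log availability of the focal
  class within the focal radius; minimum pairwise spacing enforced.
- **Pseudoabsences**: uniform over the region ≥ d from every sighting,
  outside a border band and town clusters; 500-candidate pool, 100 drawn.
- **Per-scale model**: at radius r, features are the 8 class areas in the
  disc of radius r.  Each forest trains every tree on a 70 % row subsample
  without replacement (OOB exactly 30 %); an ensemble of such forests gives
  an accuracy distribution per scale, and argmax-by-mean selects the scale
  of effect.  Accuracy = 1 − OOB misclassification under majority vote.
- **Outlier screen**: delete k rows at random (class-stratified), refit,
  repeat; regress the per-k best-replicate *excess* accuracy (best − mean)
  on k.  A significantly positive slope indicates deletable outliers.
- **Diversity**: per scale, Shannon index H = −Σ p ln p of buffer
  composition, presence vs pseudoabsence, Welch t if both groups pass
  Shapiro–Wilk, Mann–Whitney U otherwise; NMDS (Bray–Curtis, stress-1)
  summarises compositional structure.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The built-in demo configuration (256×256 grid at 100 m, planted water
preference at 1 km, 60 presences vs 60 pseudoabsences, nine radii, reduced
ensembles) runs the whole pipeline in about half a minute:

```bash
scalescape run --seed 7 --out runs/demo
```

prints

```
best scale: 0.5km (mean accuracy 0.596); top variable: water; diversity significant at 0/9 scales
```

and writes the stage outputs to `runs/demo/`, including the per-scale
accuracy table `scale_accuracy.csv`:

```
scale,inner_m,outer_m,max_acc,mean_acc,min_acc
0.5km,0.000000,500.000000,0.633333,0.595833,0.575000
1km,0.000000,1000.000000,0.575000,0.533333,0.491667
2km,0.000000,2000.000000,0.550000,0.510833,0.483333
3km,0.000000,3000.000000,0.525000,0.473333,0.433333
...
```

Reading it: accuracy peaks at the 0.5 km disc — one radius step from the
planted 1 km preference, which is within the resolution a 60-vs-60-point
demo can deliver — and decays toward the larger radii, which carry no
planted signal.  Water is the top-ranked variable at the winning scale
(`importances.csv`), exactly the planted driver.  The deletion screen
reports `"classification": "flat"` for both annular scales in
`screen_summary.json` — correct, since the demo plants no outliers.  On
this small, low-diversity-contrast demo none of the nine scales reaches
p < 0.05 in `diversity_tests.csv`; the full-size conditions below have more
power.  `run_report.json` collects the headline results plus the file
manifest and config echo.

Every stage is also available as its own subcommand
(`scalescape simulate|pseudoabs|features|model|screen|stats`) operating on
a shared output directory, and as plain library functions
(`scalescape.generate_landscape`, `scalescape.fit_scale_ensemble`, ...)
with scikit-learn-style estimators (`ScaleEnsembleClassifier`,
`SubsampleForestClassifier`) underneath.

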