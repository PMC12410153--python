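# socialconcord

How well does a machine annotator stand in for a pool of human raters
when labelling the social content of naturalistic stimuli — and do the
two stimulus models lead to the same brain maps?

`socialconcord` is a pipeline for answering that question at three
levels:

1. **Rating agreement.** For each social feature *f* (e.g. "Talking",
   "Dominant") rated across items *i*, the machine's agreement is the
   Pearson correlation r(machine_f, human-mean_f) across items. It is
   benchmarked against two human reliability indices: the
   *intersubject consistency* (the mean over raters of each rater's
   correlation with the mean of all others — the reliability of a
   single human) and the *group consistency* (the mean correlation
   between the mean ratings of two disjoint groups of g raters over all
   C(R,g)·C(R−g,g)/2 splits — the reliability of a group average, 126
   splits for R = 10, g = 5). Index sets are compared across features
   with Welch t-tests on Fisher-z transformed correlations.
2. **Representational structure.** The F×F feature correlation matrices
   of the two sources are compared by the Pearson correlation of their
   upper triangles, with significance from a seeded Mantel permutation
   test, and by principal coordinate analysis (classical MDS) on the
   correlation distance d = 1 − r: loadings of matching components are
   correlated between sources (|r|, since component signs are
   arbitrary) to reveal shared latent perceptual dimensions.
3. **fMRI encoding.** Each feature's rating time course is convolved
   with the canonical double-gamma HRF and fitted voxelwise as a simple
   regression to each subject's BOLD data; subject betas enter a
   one-sample t-test; group maps are thresholded leniently (p < 0.001
   uncorrected) and conservatively (Bonferroni voxel-level FWE,
   p < 0.05). Machine- and human-derived maps are compared by spatial
   correlation of unthresholded betas, PPV/NPV of thresholded maps
   (human maps as ground truth), and the correlation of cumulative
   tuning-breadth maps.

A synthetic-data module generates rater pools with a planted
low-dimensional latent structure and calibrated reliability, a machine
annotator with a low-end compressive bias and item refusals, and
event-related BOLD with sparse planted voxel tuning — so the whole
pipeline is testable against known ground truth.

## Worked example

```python
from socialconcord import (
    generate_rating_panel, generate_machine_ratings,
    mean_over_rounds, agreement_report,
)

panel, truth = generate_rating_panel(
    n_items=200, n_features=50, n_raters=10, k_latent=8,
    consistency_profile=0.6, seed=7)
machine = generate_machine_ratings(truth, n_rounds=5, floor_bias=0.2,
                                   fail_rate=0.03, seed=8)
rep = agreement_report(panel, mean_over_rounds(machine), group_size=5)
print(round(rep.mean_agreement, 3),
      round(rep.mean_intersubject, 3),
      round(rep.mean_group, 3),
      rep.frac_above_intersubject)
```

prints

```
0.898 0.602 0.783 1.0
```

— the machine (averaged over five rounds, mild degradation) tracks the
human population mean at r ≈ 0.90 per feature, while a single human
only reaches 0.60 (the calibration target of the generator) and a group
of five reaches 0.78; the machine beats the single-rater benchmark for
100 % of features. The same panel's correlation matrices give a Mantel
similarity near 0.99 with p = 1/(N+1) at any permutation count, because
the machine inherits the planted latent structure.

The same analyses run from the shell:

```sh
socialconcord all --seed 7 --out-dir out/
socialconcord agreement --human h.csv --machine m.csv --group-size 5
```

writing per-feature TSVs, JSON summaries and a reproducibility manifest
into the output directory. Rating tables are long CSVs with columns
`item_id, feature, rater_id|round, rating`.

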