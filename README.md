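# hubvuln

Analysis pipeline linking resting-state functional-connectivity hubs to
regional gene expression and their proportional loss in disease groups,
with a first-class synthetic-data generator standing in for clinical fMRI
and donor microarray inputs.

The pipeline:

1. **Parcellation** — seeded random-centroid Voronoi tessellation of a gray
   matter mask into K equal-size regions (`hubvuln.parcellation`), with
   coverage-based region exclusion.
2. **Motion QC** — framewise-displacement subject exclusion (> 5 mm),
   scrubbing, and a delta-BOLD motion-correlation check
   (`hubvuln.qc_motion`).
3. **Connectivity** — region time series, scale-2 MODWT wavelet
   correlations (hand-rolled MODWT in `hubvuln.wavelet`; D4 or LA8
   filters), signed Fisher-z association matrices per subject and group
   (`hubvuln.connectivity`).
4. **Expression mapping** — within-donor probe normalization, an
   interhemispheric symmetry permutation test, hemispheric mirroring,
   nearest-sample region matching, and per-region per-gene aggregation
   across donors (`hubvuln.expression_map`).
5. **Network statistics** — signed connection strength (weighted degree),
   hubs above mean + 1.5 SD of the control strengths, proportional
   connectivity loss, permutation Pearson tests, BH-FDR and Bonferroni
   corrections, groupwise Welch-t permutation tests, and a fluency
   covariance (ANCOVA-style) analysis (`hubvuln.network_stats`).
6. **Synthetic data** — band-limited low-rank factor-model BOLD signals with
   planted hubs, expression profiles coupled to connection strength at an
   exact target correlation, rank-proportional disease attenuation, motion
   traces with configurable spikes, six-donor expression tables (four
   left-hemisphere-only), and behavioural scores (`hubvuln.simulate`,
   `hubvuln.study`).

## CLI

```bash
# write a synthetic dataset
hubvuln simulate --out data/ --seed 1 --regions 50 --subjects-per-group 8

# full pipeline (QC -> parcellate -> connect -> map expression -> stats)
hubvuln run --data data/ --out out/ --k 50 --seed 1 --perms 2000
hubvuln report --results out/results.json

# individual stages
hubvuln parcellate --mask data/mask.nii --k 500 --seed 1 --out parc.nii
hubvuln qc --motion data/motion_control000.tsv
hubvuln connect --bold data/bold_control000.nii --parc parc.nii --out mat.tsv
hubvuln map-expression --parc parc.nii --samples data/samples.tsv \
    --probes data/probes.tsv --gene MAPT --out expr.tsv
```

All stage settings can also be given as a JSON config file
(`hubvuln run --config cfg.json ...`); CLI flags override it and the merged
effective configuration is written next to the results.

## Conventions

- Distances in mm (voxel indices scaled by voxel size), RAS orientation.
- MODWT uses circular boundaries; boundary-affected coefficients are
  excluded from wavelet correlations.
- Standard deviations use the n−1 denominator everywhere.
- Permutation p-values use the add-one form (b + 1) / (n + 1).
- Correlations are clipped at |r| = 1 − 1e−6 before Fisher-z where clipping
  is enabled; the flag is recorded in outputs.
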