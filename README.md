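# netbeh

Brain network connectivity–behavior mapping on volumetric data. The package
implements, end to end, a single-case analysis pipeline that links network
measures of a degenerating brain to behavioral deficits:

- **`netbeh.stats`** — scalar statistics: single-case standardization against
  a small control sample (variance-inflated t), behavioral composites from
  z-transformed corrected scores, Welch and pooled two-sample t from summary
  statistics, Pearson and partial correlation, the Fisher r-to-z transform, a
  2×2 chi-square, and a rule-based diagnostic classification.
- **`netbeh.synth`** — a fully synthetic two-group cohort (gray-matter volume
  maps, BOLD-like 4D series, diffusion-weighted series with gradient tables,
  motion and confound series, behavior tables) with planted ground truth: a
  focal atrophy region, a hub whose functional coupling to two target regions
  degrades with a latent severity, behavior scores linearly tied to severity,
  and an anisotropic tract whose principal diffusivity degrades with
  severity. Deterministic given the seed.
- **`netbeh.fmri`** — signal-level preprocessing (volume discarding, motion
  exclusion, Gaussian smoothing, linear detrend + ideal band-pass, nuisance
  regression, mfALFF) and network measures (voxel-pairwise correlation
  matrices, thresholded degree centrality, within-mask z-standardization,
  peak-seed extraction, seed FC z-maps, voxel-wise map–behavior correlation).
- **`netbeh.clusters`** — voxel-wise group t maps with residuals,
  residual-based smoothness (FWHM) estimation, Monte-Carlo cluster-extent
  thresholds (simulate–smooth–threshold–count, seedable), and connected
  component extraction with peak reporting at 6/18/26 connectivity.
- **`netbeh.dwi`** — log-linear diffusion tensor fitting, FA maps, local
  diffusion homogeneity (Kendall's W over voxel neighborhoods), deterministic
  FACT streamline tracking with angle/FA stopping rules, ROI-to-ROI tract
  masks, group count-map thresholding, and tract-integrity statistics.
- **`netbeh.pipeline`** — the orchestrator: behavior correction → atrophy
  network (cluster-corrected group contrast) → within-mask degree maps →
  degree contrast and seed extraction → degree–behavior correlation → seed FC
  z-maps → FC–behavior cluster maps → confound-controlled validation (four
  covariates, singly and jointly, plus a first-observation subset) →
  non-semantic specificity tests → tensor/FA/LDH → tract construction between
  the seed region and each FC cluster → integrity group tests and behavior
  correlations. Emits NIfTI maps, TSV/JSON tables, a manifest, and a
  markdown report.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including the
multi-cohort parameter-recovery and null-calibration simulations (several
minutes of runtime); the other test modules are fast unit/property tests.

## CLI

```sh
netbeh synth --config cfg.yaml --seed 7 --out cohort/   # synthetic cohort
netbeh run --seed 7 --out results/                      # full pipeline
netbeh report results/                                  # print the report
netbeh alphasim --mask m.nii.gz --fwhm 8 --voxel-p 0.05 --alpha 0.05 \
    --iters 1000 --seed 1
netbeh preproc --bold b.nii.gz --tr 2.0 --out clean.nii.gz
netbeh degree --bold clean.nii.gz --mask m.nii.gz --r-thresh 0.10 --out d.nii.gz
netbeh seedfc --bold clean.nii.gz --mask m.nii.gz --seed-json seed.json --out z.nii.gz
netbeh behcorr --maps z1.nii.gz --maps z2.nii.gz ... --scores s.tsv \
    --mask m.nii.gz --out r.nii.gz
netbeh tract --dwi d.nii.gz --bvec d.bvec --bval d.bval \
    --roi-a a.nii.gz --roi-b b.nii.gz --seeds 100 --angle 45 --fa-min 0.15 \
    --seed 1 --out tract.nii.gz
```

`netbeh run` accepts a YAML config mirroring `netbeh.pipeline.PipelineConfig`
(thresholds, smoothing FWHMs, band, Monte-Carlo iterations, and a nested
`synthetic:` section for the cohort generator).

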