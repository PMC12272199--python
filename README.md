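# widedecode

How much stimulus-specific information do brain activity maps carry, and
where does it live? Task-fMRI practice thresholds mass-univariate
t-statistic maps and keeps the suprathreshold "blobs", implicitly
treating subthreshold voxels as noise. `widedecode` implements a simple,
deliberately transparent decoding framework for testing that assumption:
the voxels of a paired contrast map are binned into deciles of |t|, each
decile — including the "noise" decile with t ≈ 0 — becomes a linear
decoder with the signed t values as weights, and each decoder's
across-subject discrimination is measured as an out-of-sample AUC. If
the lowest deciles decode, task information is spread far beyond the
blobs. A second arm asks how this widespread information behaves under
propofol sedation, using seed-derived task vectors, per-state decoding,
and intersubject functional connectivity (ISFC).

The package is aimed at neuroimaging methods researchers: it runs on
NIfTI volumes or plain subjects × voxels matrices, and ships a
synthetic-data module with known ground truth so every estimator can be
validated end-to-end without access to any real dataset.

## What's inside

- `widedecode.decoders` — voxel-wise paired t-maps, t→r conversion,
  |t|-decile binning with deterministic tie-breaking, dot-product
  scoring.
- `widedecode.bootstrap` — Mann–Whitney AUC, the **floor-free 0.632+
  bootstrap** (θ̂₀.₆₃₂₊ = (1−ŵ)·θ̂app + ŵ·θ̂boot with ŵ = 0.632/(1−0.368·R̂),
  no max(·, 0.5) floor, so estimates may honestly dip below chance),
  nested bootstrap covariances, and motion orthogonalization of decoder
  scores.
- `widedecode.summaries` — AUC squeezing, logit transforms,
  covariance-weighted GLS with the `[1, decile] ⊗ [states]` Kronecker
  design, fixed-effect consolidation across contrasts.
- `widedecode.pca_kl` — across-subject PCA via SVD, phase-scrambled
  surrogates, parallel analysis, the closed-form multivariate Gaussian
  KL decision rule, and the univariate signed-t reference decoder.
- `widedecode.perturb` — SNR-scaled noise injection, voxel-count
  subsampling, voxel-count-matched region comparisons.
- `widedecode.isfc` — seed task vectors, GLM beta maps, per-state decile
  and whole-ROI decoding, within-subject FC and ISFC with Fisher-z
  averaging, and a state permutation test.
- `widedecode.synthetic` — map-study and sedation-study generators with
  stored ground truth.
- `widedecode.io` / `widedecode.cli` — NIfTI/TSV/JSON readers and
  writers and a `widedecode` command-line entry point
  (`simulate-maps`, `simulate-sedation`, `decile-decode`, `pca-decode`,
  `perturb`, `sedation-decode`, `isfc`, `summarize`).

See `docs/methods.md` for the estimators, their assumptions, and what
the synthetic generators do and do not emulate.

## Worked example

Simulate a study in which a weak effect (per-voxel SD 0.3, noise SD 1 —
mostly subthreshold univariately at n = 30) is spread over all 5,000
voxels, then estimate each decile decoder's out-of-sample AUC:

```python
import widedecode as wd

study = wd.gen_map_study(wd.MapStudyConfig(
    n_subjects=30, n_voxels=5000, signal_profile="widespread",
    effect_scale=0.3, seed=11))
res = wd.bootstrap_632plus(study, wd.BootstrapConfig(n_replicates=100, seed=12))
for d in range(10):
    print(f"decile {d+1:2d}: apparent={res.theta_app[d]:.3f}  "
          f"oob={res.theta_boot[d]:.3f}  auc_632plus={res.theta_632plus[d]:.3f}")
```

```
decile  1: apparent=0.679  oob=0.622  auc_632plus=0.638
decile  2: apparent=0.887  oob=0.734  auc_632plus=0.774
decile  3: apparent=0.969  oob=0.861  auc_632plus=0.894
decile  4: apparent=1.000  oob=0.933  auc_632plus=0.955
decile  5: apparent=1.000  oob=0.975  auc_632plus=0.984
decile  6: apparent=1.000  oob=0.993  auc_632plus=0.995
decile  7: apparent=1.000  oob=0.999  auc_632plus=0.999
decile  8: apparent=1.000  oob=1.000  auc_632plus=1.000
decile  9: apparent=1.000  oob=1.000  auc_632plus=1.000
decile 10: apparent=1.000  oob=1.000  auc_632plus=1.000
```

Decile 1 holds the voxels a thresholded analysis would discard
(|t| ≈ 0), yet it discriminates the two conditions at AUC 0.64 —
integrating ~500 weakly informative voxels is enough. The gap between
the apparent and the 0.632+ columns is the optimism the bootstrap
removes; on a no-signal study the apparent AUC of the top decile still
approaches 1 while the 0.632+ estimate stays at chance.

The same objects drive the sedation arm, e.g.

```python
study = wd.gen_sedation_study(wd.SedationStudyConfig(seed=1))
res = wd.isfc.sedation_decile_decoding(study, "deep",
                                       wd.BootstrapConfig(n_replicates=60, seed=2))
```

or, from a shell, `widedecode simulate-sedation --out sed --seed 1`
followed by `widedecode sedation-decode --study sed --out sed_auc.tsv`.

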