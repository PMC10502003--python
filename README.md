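# segensemble

Label fusion, quality metrics and robustness analytics for **ensembles of
3D organ segmentation masks**.

## The problem

A set of independently trained segmentation networks ("deep ensemble")
produces J candidate binary masks per image. Averaging them improves mean
accuracy — but the more consequential effect is *robustness*: single
models occasionally fail catastrophically on individual images (distant
spurious components, gross dropouts), and a fused consensus suppresses
almost all of these failures. This package implements the mask-level
computational machinery to quantify that:

* **Fusion schemes** — probability averaging with a threshold
  `S_ens = 𝟙[(1/J) Σ_m S_m ≥ p_thr]` (default `p_thr = 0.35`),
  strict-majority label voting, the STAPLE expectation–maximization
  algorithm (simultaneous truth and performance level estimation, jointly
  estimating a consensus probability field `W_i` and each rater's
  sensitivity `p_j` / specificity `q_j`), and a regression combiner that
  predicts each model's ground-truth Dice from its pairwise Dices,
  `DSC(S_m, GT) ≈ α_m + Σ_{n≠m} β_mn DSC(S_m, S_n)`, and selects the
  argmax.
* **Metrics** — DSC, relative volume difference (RVD), average and
  maximum symmetric surface distance (ASSD / MSSD, i.e. the Hausdorff
  distance of the boundaries), spacing-aware in mm, with explicit
  empty-mask semantics.
* **Robustness analytics** — per-organ percentile outlier boundaries
  (DSC below its 5th percentile, RVD/ASSD/MSSD above their 95th),
  high-risk images (≥ 1 model with an outlier metric), ensemble rescue
  rates, ensemble gain `g = L_ens − ⟨L⟩` (losses: Dice loss `1 − DSC`,
  RVD, ASSD, MSSD) with York line fits (errors in both coordinates), and
  ensemble-size subsampling experiments.
* **Synthetic studies** — a generator of ground-truth phantoms and
  simulated model outputs whose statistical structure matches trained
  ensembles: sub-voxel per-model disagreement, a correlated per-image
  error shared by all models, and rare independent catastrophic failures.
  An iid rater model with known sensitivity/specificity supports STAPLE
  parameter-recovery tests.

Masks live on a common grid as NIfTI volumes (or in memory); a JSON/CSV
manifest ties images × models × references together. No resampling or
registration is performed — geometry mismatches are errors.

## A worked example

```python
import numpy as np
import segensemble as se

gt = se.make_phantom(se.PhantomSpec(grid_shape=(48, 48, 48),
                                    semi_axes=(12, 10, 9)))
masks = [se.simulate_model_output(gt, se.ModelProfile(), rng=seed)
         for seed in range(8)]

fused = se.fuse_average(masks, p_thr=0.35)
print("single-model DSC:", np.round([se.dice(m, gt) for m in masks[:3]], 3))
print("ensemble DSC:    ", round(se.dice(fused, gt), 3))

record = se.evaluate(fused, gt, organ="phantom", image_id="demo",
                     source_id="ensemble")
print("ASSD %.2f mm, MSSD %.2f mm" % (record.assd_mm, record.mssd_mm))
```

prints

```
single-model DSC: [0.886 0.942 0.943]
ensemble DSC:     0.958
ASSD 0.32 mm, MSSD 1.41 mm
```

— the fused mask beats each individual model, and its Hausdorff distance
(1.4 mm) shows no trace of any spurious component. `examples/` holds one
short script per capability (metrics, fusion schemes, STAPLE recovery,
the robustness report, threshold/size sweeps); each prints the numbers it
computes with a line on what they mean. A thin CLI mirrors the flow:

```bash
segensemble simulate --out study/ --seed 1 --n-images 10
segensemble fuse --manifest study/manifest.json --method average --out fused/
segensemble evaluate --manifest study/manifest.json --pred-dir fused/ --out metrics.csv
segensemble robustness-report --metrics metrics.csv --out report.json
```

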