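# dsanet

Tumor segmentation and treatment-response prediction for contrast
angiography (DSA) videos, exercised end to end on a synthetic phantom
cohort with known generative structure.

The package contains:

- **`dsanet.preprocess`** — video ingestion (PNG stacks or uncompressed
  AVI), black-border removal, min-max normalization, resizing, automatic
  key-frame selection (peak opacification relative to the pre-contrast
  frame), and assembly of the ±1 augmentation frames and the 10-frame
  temporal window with its frame-difference target.
- **`dsanet.synthetic`** — seeded phantom generator: liver silhouette,
  branching vessel tree and tumor blushes riding a gamma-variate bolus
  curve, moving confounders (bowel/diaphragm) outside the liver, Gaussian
  noise; plus a cohort generator with clinical covariates, a logistic
  response-label model, and exponential progression-free survival with a
  programmed hazard ratio.
- **`dsanet.segnet`** — the multi-task segmentation network: a U-Net
  baseline plus a temporal-difference encoder (TDL), a liver-region
  subnet (LRS), and the fused variant (FFS), co-trained under the
  composite loss `λ0·L_ltd + λ1·L_lrs + L_seg` (defaults a=0.5, λ0=0.1,
  λ1=1) with five-fold patient-level cross-validation.
- **`dsanet.respnet`** — the response classifier: a ResNet-style image
  branch on `{key frame, key frame × mask, mask}` channels, an MLP on
  tabular clinical covariates, and a fused linear head; input variants
  `KF`, `clinical`, `KF_mask`, `KF_mask_clinical` with predicted or
  ground-truth masks.
- **`dsanet.evalstats`** — Dice, pixel-level confusion metrics,
  lesion-level sensitivity/FPR on 8-connected components, percentile
  bootstrap CIs, ROC AUC, DeLong's paired test, Kaplan–Meier curves with
  the log-rank test, and subgroup (size/multiplicity/FOV) reports.
- **`dsanet.cli`** — one-command orchestration with a manifest, config
  hashing, and seeded reproducibility.

The networks run on a small NumPy layer library with explicit
backpropagation (`dsanet.nn`) so everything trains on a single CPU with no
deep-learning framework dependency.

## CLI

```bash
# full pipeline on the built-in desk profile (40 phantoms, 64×64)
dsanet run --seed 1 --out runs/desk

# individual stages, custom config
dsanet simulate --config my.yaml
dsanet train-seg --config my.yaml --variant ffs --folds 5
dsanet train-clf --config my.yaml --variant KF_mask_clinical --mask-source pred
dsanet evaluate --config my.yaml
dsanet report --config my.yaml
```

Each run directory holds `manifest.json` (stage provenance),
`cv_metrics.csv`, `clf_predictions.csv`, `metrics.json`,
`per_patient_metrics.csv`, and Kaplan–Meier curves (`km_curves.csv/png`).
Rerunning a completed stage with an unchanged config is a no-op unless
`--force` is given.

A config file is plain YAML; see `DESK_CONFIG` in `dsanet/config.py` for
the full set of keys.

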