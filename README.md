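# hbvision

A tested, reusable pipeline for image-based non-invasive hemoglobin (Hb)
estimation: from synthetic eyelid/fingernail photographs through ROI
refinement, hue-histogram + PCA feature engineering and regression, to
clinical corridor discretization and a deterministic quality-of-life-augmented
decision layer compared against clinician labels.

## Modules

| Module | What it does |
| --- | --- |
| `hbvision.synthetic_data` | Cohort generator (three subgroups with truncated-normal Hb, repeat visits, anemia threshold 6.21 mmol/L), Hb-linked EORTC Global Health / Fatigue scores, a documented clinician labeling rule, and rendered image patches with a monotone hue–Hb link, lighting noise and over-segmented coarse masks. |
| `hbvision.roi_refinement` | Iterative boundary erosion toward a 30 % retained-pixel target (fingernails); Sobel + Otsu edge detection, Hough circle vote and lower-segment extraction (eyelids), with fallback to the eroded coarse mask. |
| `hbvision.chromatic_features` | RGB → HSV hue conversion (achromatic pixels excluded), normalized 36-bin hue histograms, and SVD-based PCA compression with a fixed sign convention. |
| `hbvision.predictors` | Closed-form ridge regression (unpenalized intercept, internal standardization) and histogram gradient-boosted trees, each with a three-class corridor classification variant (severity tie-break Red > Yellow > Green). |
| `hbvision.evaluation` | Patient-ID-grouped 10-fold cross-validation, within-fold median aggregation per (patient, visit), residual SD / MSE / R², confusion matrices, F1 scores, Type-1/Type-2 error rates, and a hard leakage audit. |
| `hbvision.corridor_decision` | Hb corridors (Red < 4.5, Yellow 4.5–6.0, Green > 6.0 mmol/L), QoL cut-point strata, equal-weight majority vote with conservative tie-break, and concordance reporting against clinician labels. |
| `hbvision.pipeline` / `hbvision.cli` | End-to-end orchestration (simulate → refine → featurize → evaluate → decide) with YAML configs, content-hashed manifests and reproducible seeds. |

## CLI

```bash
# full run from a YAML config (see tests/test_pipeline.py for an example)
hbvision all --config config.yaml --seed 1 --out runs/demo

# individual stages operate on the same run directory
hbvision simulate --config config.yaml --out runs/demo
hbvision refine   --config config.yaml --out runs/demo
hbvision featurize --config config.yaml --out runs/demo
hbvision evaluate --config config.yaml --out runs/demo

# decision layer on an arbitrary prediction table
hbvision decide --input preds.csv --out decisions.csv
```

Artifacts: cohort and feature tables as CSV, images/masks as PNG,
ground-truth sidecars, models and evaluation reports as JSON, plus a
`manifest.json` with SHA-256 content hashes. Identical config + seed yields
identical metric outputs.

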