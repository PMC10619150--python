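# mobilemfs

Lightweight attention CNNs for leaf-disease image classification.

Identifying foliar diseases from leaf photographs is a nine-way image
classification problem (eight apple diseases — Alternaria leaf spot, brown
spot, frogeye leaf spot, grey spot, mosaic, powdery mildew, rust, scab — plus
healthy leaves) whose discriminative evidence is the lesion phenotype: spot
color, size, count, ringing, chlorosis, vein whitening.  This package
implements **MobileNet-MFS**, a MobileNet v3-Large variant for that task,
together with everything needed to exercise it end to end on a single CPU:

- **FSCA (fused spatial-channel attention)** — the block at the heart of the
  architecture.  Stage one pools the feature map along each spatial axis,
  concatenates the two directional profiles into a `1×(H+W)×C` strip,
  normalizes it through a reduce/expand 1×1 convolution pair and multiplies
  the per-row and per-column sigmoid weights back onto the input
  (coordinate-attention style).  Stage two takes the per-location channel max
  and mean, fuses them with a single-output-channel k×k convolution and
  gates every location by the resulting sigmoid map.  Formally, stage one
  computes `y[i,j,c] = x[i,j,c]·σ(r[i,c])·σ(s[j,c])` and stage two
  `z[i,j,c] = y[i,j,c]·σ(w[i,j])`.
- **Multi-scale front end** — parallel 1×1/3×3/5×5/7×7 convolutions on the
  input image, concatenated and fused by a 1×1 convolution, placed ahead of
  the backbone stem.
- **Backbone assembly** — declarative inverted-residual bottlenecks
  (expand → depthwise → attention → linear project, residual when stride 1
  and widths match), the published v3-Large layout, and exact parameter /
  multiply-accumulate accounting.
- **Baseline attention blocks** (SE, ECA, CBAM, coordinate attention) behind
  one registry, for ablation sweeps.
- **Data tooling** — stratified 4:1 split (`test = floor(n/5)`), ×3
  augmentation bookkeeping, CSV manifests, and a deterministic synthetic
  leaf-disease generator that draws the nine lesion phenotypes procedurally,
  so the full train/evaluate/explain pipeline runs with no external data.
- **Evaluation** — confusion matrix, per-class precision/recall/F1 with
  weighted and macro averages, one-vs-rest ROC curves and trapezoidal AUC.
- **Grad-CAM** — gradient-weighted class-activation heat maps and overlay
  rendering for lesion-localization inspection.

The whole stack runs on a compact NumPy reverse-mode autodiff engine
(`mobilemfs.nn`) — no GPU framework required.

## Worked example

```python
from mobilemfs import (build_mobilenet_v3_large, build_mobilenet_mfs,
                       count_params, count_macs)

base = build_mobilenet_v3_large(num_classes=9)
mfs = build_mobilenet_mfs(num_classes=9)
print(count_params(base))                 # 4213561
print(round(count_macs(base, (224, 224)) / 1e6, 2))   # 215.32
print(count_params(mfs))                  # 3001523
```

`4213561` is the exact trainable-scalar count of MobileNet v3-Large with a
9-way classifier (4.21 M); `215.32` is its multiply-accumulate count at
224×224 in MFLOPs (one MAC counted once, normalization/activation excluded).
Swapping SE for FSCA and adding the front end *reduces* the total to
3.00 M, because FSCA's reduce/expand bottleneck (ratio 32) is much cheaper
than SE's fully connected pair.

The same numbers from the shell, plus a per-layer table:

```bash
mobilemfs stats --model mobilenet_v3 --num-classes 9 --per-layer
```

An end-to-end run on synthetic data:

```bash
mobilemfs synth --out data --n-per-class 50 --image-size 96 --seed 1
mobilemfs split --data data --seed 1
mobilemfs train --manifest data/manifest.csv --model mobilenet_mfs_small \
                --epochs 15 --out run --seed 1
mobilemfs evaluate --manifest data/manifest.csv \
                   --checkpoint run/checkpoint.npz --out eval
mobilemfs gradcam --checkpoint run/checkpoint.npz \
                  --image data/Rust/rust_0000.png --out cam
```

`evaluate` prints a JSON report (accuracy, per-class precision/recall/F1/AUC,
confusion matrix); `gradcam` writes `heatmap.png` and `overlay.png`.

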