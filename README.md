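# pics-wbc

Label-free white-blood-cell screening on quantitative phase images, for
researchers in computational microscopy and hematology image analysis.

Wright-stained blood smears are the workhorse of leukocyte diagnostics, but
staining and manual reading tie the assay to a clinical lab. Phase imaging
with computational specificity (PICS) replaces the stain with computation:
a phase-shifting interferometric microscope measures the optical pathlength
field φ(x, y) of an unlabeled smear, and learned models recover the
stain-specific information. This package implements that pipeline end to
end:

1. **Phase reconstruction** — four interferograms at delays kπ/2 are
   inverted in closed form: Δφ = atan2(I₃−I₁, I₀−I₂), with the amplitude
   ratio β = |U_s|/|U_i| recovered from the fringe modulation and
   φ = atan2(β sin Δφ, 1 + β cos Δφ).
2. **Virtual staining** — a conditional GAN (pix2pix-style) maps phase to a
   Wright-stain brightfield rendering by the objective
   L_cGAN(G,D) = E[log D(x,y)] + E[log(1−D(x,G(x,z)))] plus λ‖G(x)−y‖₁,
   λ = 100.
3. **Detection** — an anchor-based detector localizes and classifies
   neutrophils, eosinophils, lymphocytes and monocytes (focal + smooth-L1
   loss, early stopping on validation mAP).
4. **Segmentation** — a U-Net produces a binary WBC mask (MSE loss, early
   stopping on validation loss).
5. **Fusion + voting** — boxes and mask combine into a per-pixel semantic
   map {background, 4 WBC classes}; the maps of five independently trained
   model pairs are ensembled by pixel-wise majority voting.
6. **Evaluation** — per-class AP / mAP at IoU 0.5, pixel-wise
   precision/recall/F1 (macro averages include background), and mean ±
   population-std aggregation over repeated splits.

Because no clinical data ship with the package, `pics.smear_sim` generates
fully annotated synthetic smear fields (RBC background, four WBC classes at
normal differential proportions, matched phase maps, interferograms with
halo shading and noise, boxes, masks, semantic maps), and the whole pipeline
runs against them. The networks are compact numpy implementations with
hand-written gradients — no GPU or deep-learning framework required.

## Worked example

```python
import numpy as np
from scipy import ndimage
from pics.smear_sim import SmearConfig, render_smear
from pics.slim_recon import estimate_amplitude_ratio
from pics.detection import Detection
from pics.fusion import fuse
from pics.metrics import pixel_scores, macro_f1

config = SmearConfig(field_size=(80, 80), pixel_size=0.55, rbc_density=12.0, seed=7)
sample = render_smear(config)
print("ground-truth cells:", [(b.wbc_class, b.box) for b in sample.boxes])

recon = estimate_amplitude_ratio(sample.stack)
halo_truth = sample.phase_gt.phi - 0.25 * ndimage.gaussian_filter(sample.phase_gt.phi, 8.0)
rms = np.sqrt(np.mean((recon.delta_phi - halo_truth) ** 2))
print(f"RMS reconstruction error vs halo-shaded truth {rms:.4f} rad")

# an imperfect detector: the lymphocyte is missed, one box slightly offset
dets = [Detection(box=(13.0, 15.0, 40.0, 41.0), wbc_class=1, confidence=0.93),
        Detection(box=sample.boxes[1].box, wbc_class=1, confidence=0.88)]
semantic = fuse(sample.binary_mask, dets)
scores = pixel_scores(semantic, sample.semantic_gt)
print("per-class F1:", {k: round(v, 3) for k, v in scores.f1.items()})
print("macro F1 (incl. background):", round(macro_f1(scores), 3))
```

prints

```
ground-truth cells: [(1, (15.0, 17.0, 39.0, 40.0)), (1, (59.0, 34.0, 79.0, 54.0)), (3, (40.0, 50.0, 56.0, 67.0))]
RMS reconstruction error vs halo-shaded truth 0.0093 rad
per-class F1: {0: 0.981, 1: 1.0, 2: 1.0, 3: 0.0, 4: 1.0}
macro F1 (incl. background): 0.796
```

The field holds two neutrophils (class 1) and a lymphocyte (class 3). The
reconstruction error is set by the simulated shot noise (σ = 0.01 on
intensities ≈ 0.005 rad phase-equivalent). In the fusion step, mask pixels
of the missed lymphocyte fall inside no box and drop to background — class 3
scores F1 = 0 while both neutrophils survive, and the macro F1 over all
five classes is 0.796.

The same stages are available from the shell:

```bash
pics simulate --n 60 --test 10 --repeats 5 --field-size 80 --pixel-size 0.55 --seed 7 --out data/
pics reconstruct --stack data/00000_s0.tif --out recon/
pics pipeline --data data/ --out runs/ --version brightfield --seed 1
pics compare  --data data/ --out runs/ --seed 1
```

`pics pipeline` trains detector + segmenter per repeat (plus the translator
in `--version translated`), evaluates every repeat on the fixed test set,
majority-votes the ensemble and writes `report.json` / `report.md` with
mean ± std rows.

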