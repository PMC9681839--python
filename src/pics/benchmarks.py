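"""Reference benchmark scores for the clinical WBC-PICS study design.

These are the published per-test-split scores of the full-scale pipeline on
clinical Wright-stained smears (five random train/validation splits, one
fixed test set; three input versions: SLIM phase, true brightfield, and
GAN-translated brightfield).  They are bundled for two purposes:

* validating this package's aggregation conventions — the printed "mean ±
  std" columns are reproduced exactly by arithmetic mean and population
  (divide-by-n) standard deviation;
* providing context for the scaled-down synthetic runs, which target the
  same metrics but make no claim of reproducing these numbers.

Note: in the localization table the printed mean of the translated row
(0.7469) differs from the mean of its own per-test values (0.74712) by more
than print rounding can explain; the recomputed value is authoritative here.
"""

from __future__ import annotations

# Localization / classification: per-test-split mAP, printed mean ± std
LOCALIZATION_MAP = {
    "slim": {"per_test": (0.7581, 0.7543, 0.7301, 0.7196, 0.6696), "mean": 0.7263, "std": 0.032},
    "brightfield": {"per_test": (0.8476, 0.8545, 0.8544, 0.8736, 0.8112), "mean": 0.848, "std": 0.02},
    "translated": {"per_test": (0.7742, 0.7805, 0.6877, 0.7569, 0.7363), "mean": 0.7469, "std": 0.03},
}

# Semantic segmentation: per-test-split pixel-wise F1, printed mean ± std
SEGMENTATION_F1 = {
    "slim": {"per_test": (0.785, 0.769, 0.749, 0.762, 0.709), "mean": 0.7548, "std": 0.026},
    "brightfield": {"per_test": (0.81, 0.819, 0.82, 0.831, 0.796), "mean": 0.8152, "std": 0.012},
    "translated": {"per_test": (0.796, 0.81, 0.749, 0.742, 0.735), "mean": 0.7664, "std": 0.031},
}

# Majority voting: per-class F1 (background, neutrophil, eosinophil,
# lymphocyte, monocyte) and the printed 5-class average
MAJORITY_VOTING_F1 = {
    "slim": {"per_class": (0.996, 0.716, 0.925, 0.591, 0.701), "average": 0.786},
    "brightfield": {"per_class": (0.997, 0.755, 0.901, 0.696, 0.797), "average": 0.829},
    "translated": {"per_class": (0.997, 0.685, 0.867, 0.685, 0.757), "average": 0.798},
}
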