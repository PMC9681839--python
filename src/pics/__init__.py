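"""Label-free white-blood-cell analysis via phase imaging with computational specificity.

The package mirrors a full hematology screening pipeline on unstained blood
smears: four phase-shifted interferograms are inverted into a quantitative
phase map (``slim_recon``); a conditional GAN translates phase into a
Wright-stain-like brightfield rendering (``translation``); an anchor-based
detector localizes and classifies white blood cells (``detection``) while a
U-Net produces a binary WBC mask (``segmentation``); box labels and mask are
fused into a per-pixel semantic map and ensembled by pixel-wise majority
voting (``fusion``); ``metrics`` provides the mAP / pixel-wise F1 evaluation
stack, and ``smear_sim`` generates fully annotated synthetic smear fields so
the whole pipeline runs without clinical data.
"""

import importlib

__version__ = "0.1.0"

_SUBMODULES = {
    "benchmarks",
    "detection",
    "fusion",
    "harness",
    "metrics",
    "pipeline",
    "protocols",
    "segmentation",
    "slim_recon",
    "smear_sim",
    "translation",
}


def __getattr__(name):
    if name in _SUBMODULES:
        return importlib.import_module(f"pics.{name}")
    raise AttributeError(f"module 'pics' has no attribute {name!r}")

WBC_CLASSES = {1: "neutrophil", 2: "eosinophil", 3: "lymphocyte", 4: "monocyte"}

__all__ = [
    "WBC_CLASSES",
    "detection",
    "fusion",
    "metrics",
    "segmentation",
    "slim_recon",
    "smear_sim",
    "translation",
]
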