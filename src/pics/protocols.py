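"""Canned study protocols at CPU-friendly problem sizes.

The clinical-scale study design (504 brightfield fields, five repeated
train/validation splits, one fixed test set, large pretrained backbones) is
not reproducible on a desktop CPU; :func:`scaled_study` runs the same
protocol end to end at a reduced size chosen once for this package:
80 x 80-pixel fields at 0.55 µm/px, 200 train / 25 validation / 20 test
images, five repeats, and the compact network variants.  Its numbers are
sanity bars for the pipeline mechanics, not reproductions of the
clinical-scale scores.
"""

from __future__ import annotations

import json
from pathlib import Path

from pics import metrics
from pics.detection import DetectorTrainConfig
from pics.pipeline import RunConfig, run_pipeline
from pics.segmentation import SegTrainConfig
from pics.smear_sim import SmearConfig, make_dataset

__all__ = ["SCALED_SMEAR_CONFIG", "scaled_study"]

#: simulation conditions of the scaled study (fixed; see docs/methods.md)
SCALED_SMEAR_CONFIG = SmearConfig(
    field_size=(80, 80),
    pixel_size=0.55,
    rbc_density=12.0,
)


def scaled_study(
    work_dir: str | Path,
    seed: int = 1,
    n_images: int = 245,
    n_test: int = 20,
    n_repeats: int = 5,
    image_version: str = "brightfield",
) -> dict:
    """Generate a dataset, run the multi-repeat pipeline, return key numbers.

    With the defaults the dataset splits into 200 train / 25 validation per
    repeat and a fixed 20-image test set.  Returns a dict with per-repeat
    validation mAP, per-repeat test mAP and macro F1, their aggregates, and
    the majority-voting scores.
    """
    work = Path(work_dir)
    data_dir = work / "data"
    if not (data_dir / "annotations.json").exists():
        make_dataset(
            data_dir,
            n_images=n_images,
            n_test=n_test,
            n_repeats=n_repeats,
            config=SCALED_SMEAR_CONFIG,
            seed=seed,
            force=True,
        )
    config = RunConfig(
        data_dir=data_dir,
        out_dir=work / "runs",
        image_version=image_version,
        detector=DetectorTrainConfig(learning_rate=2e-3, max_epochs=40),
        segmenter=SegTrainConfig(
            learning_rate=1e-3, max_epochs=20, base_channels=4, convs_per_block=1
        ),
        seed=seed,
    )
    report = run_pipeline(config)

    val_maps = []
    for r in range(n_repeats):
        rec = json.loads(
            (work / "runs" / image_version / f"rep{r}" / "val_metrics.json").read_text()
        )
        val_maps.append(rec["best_val_mAP"])
    f1_mean, _ = metrics.aggregate([p["macro_f1"] for p in report.per_repeat])
    return {
        "val_mAP_per_repeat": val_maps,
        "test_mAP_per_repeat": [p["mAP"] for p in report.per_repeat],
        "test_macro_f1_per_repeat": [p["macro_f1"] for p in report.per_repeat],
        "aggregate": report.aggregate,
        "voting_per_class_f1": report.voting["per_class_f1"],
        "voting_macro_f1": report.voting["macro_f1"],
        "voting_f1_change": report.voting["macro_f1"] - f1_mean,
        "n_train": len(json.loads((data_dir / "splits.json").read_text())["repeats"][0]["train_ids"]),
        "n_test": n_test,
        "report": report.to_dict(),
    }
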