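"""End-to-end orchestration of the WBC screening pipeline.

For a dataset on disk (see :func:`pics.smear_sim.make_dataset`) and one of
three input versions — ``slim`` (reconstructed phase replicated to three
channels), ``brightfield`` (the stain rendering), or ``translated`` (the
cGAN's output from phase) — the pipeline repeats, for each train/validation
split: translator training (translated mode only), detector and segmenter
training, then inference on the fixed test set, box–mask fusion and
per-repeat evaluation.  The per-repeat semantic maps are finally combined by
pixel-wise majority voting and re-evaluated.  All stage artifacts
(detections JSON, mask/semantic PNGs, loss logs) are persisted so the report
can be recompiled from disk, and all randomness flows from the single run
seed through named per-stage, per-repeat substreams.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from pics import fusion, metrics
from pics.detection import Detection, DetectorTrainConfig, detect, train_detector
from pics.segmentation import SegTrainConfig, segment, train_segmenter
from pics.slim_recon import InterferogramStack, reconstruct_phase
from pics.smear_sim import CLASS_NAMES, load_dataset
from pics.translation import (
    TranslationTrainConfig,
    normalize_phase,
    train_translator,
    translate,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_versions", "compile_report"]

_STAGE_IDS = {"translate": 1, "detect": 2, "segment": 3}
VERSIONS = ("slim", "brightfield", "translated")


def _substream_seed(seed: int, stage: str, repeat: int) -> int:
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage], int(repeat)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    data_dir: str | Path
    out_dir: str | Path
    image_version: str = "brightfield"
    repeats: list[int] | None = None  # 0-based repeat indices; None = all
    detector: DetectorTrainConfig = field(default_factory=DetectorTrainConfig)
    segmenter: SegTrainConfig = field(default_factory=SegTrainConfig)
    translator: TranslationTrainConfig = field(default_factory=TranslationTrainConfig)
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.image_version not in VERSIONS:
            raise ValueError(f"image_version must be one of {VERSIONS}")
        if self.repeats is not None and len(self.repeats) < 1:
            raise ValueError("repeats must contain at least one index")


@dataclass
class RunReport:
    image_version: str
    per_repeat: list[dict]
    aggregate: dict
    voting: dict

    def to_dict(self) -> dict:
        return {
            "image_version": self.image_version,
            "per_repeat": self.per_repeat,
            "aggregate": self.aggregate,
            "voting": self.voting,
        }

    def to_markdown(self) -> str:
        rows = [f"# Run report — {self.image_version}", "",
                "| repeat | test mAP | test macro F1 |", "|---|---|---|"]
        for r in self.per_repeat:
            rows.append(f"| {r['repeat'] + 1} | {r['mAP']:.4f} | {r['macro_f1']:.4f} |")
        agg = self.aggregate
        rows.append(
            f"| mean ± std | {agg['mAP']['mean']:.4f} ± {agg['mAP']['std']:.3f} "
            f"| {agg['macro_f1']['mean']:.4f} ± {agg['macro_f1']['std']:.3f} |"
        )
        rows += ["", "| class | voting F1 |", "|---|---|"]
        names = {0: "background", **CLASS_NAMES}
        for k, v in self.voting["per_class_f1"].items():
            rows.append(f"| {names[int(k)]} | {v:.4f} |")
        rows.append(f"| **macro** | {self.voting['macro_f1']:.4f} |")
        return "\n".join(rows) + "\n"


# --------------------------------------------------------------------------
# dataset access


def _load_arrays(data_dir: Path):
    import imageio.v3 as iio
    import tifffile

    coco, split = load_dataset(data_dir)
    boxes_by_img = {img["id"]: [] for img in coco["images"]}
    for ann in coco["annotations"]:
        x, y, w, h = ann["bbox"]
        boxes_by_img[ann["image_id"]].append(((x, y, x + w, y + h), ann["category_id"]))
    arrays = {}
    for img in coco["images"]:
        i = img["id"]
        sid = f"{i:05d}"
        frames = np.stack(
            [tifffile.imread(data_dir / f"{sid}_s{k}.tif").astype(np.float64) for k in range(4)]
        )
        arrays[i] = {
            "bf": iio.imread(data_dir / f"{sid}_bf.png").astype(np.float64) / 255.0,
            "stack": InterferogramStack(frames),
            "mask": (iio.imread(data_dir / f"{sid}_mask.png") > 127).astype(np.uint8),
            "sem": iio.imread(data_dir / f"{sid}_sem.png").astype(np.uint8),
            "boxes": boxes_by_img[i],
        }
    return coco, split, arrays


def _phase_images(arrays) -> dict[int, np.ndarray]:
    phases = {i: reconstruct_phase(a["stack"]).phi for i, a in arrays.items()}
    lo, hi = np.percentile(np.stack(list(phases.values())), [1, 99])
    return {i: normalize_phase(p, lo, hi) for i, p in phases.items()}


def _to_rgb(img: np.ndarray) -> np.ndarray:
    return np.repeat(img[..., None], 3, axis=2) if img.ndim == 2 else img


# --------------------------------------------------------------------------
# the run


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage for the configured image version; return the report."""
    data_dir = Path(config.data_dir)
    out = Path(config.out_dir) / config.image_version
    out.mkdir(parents=True, exist_ok=True)

    coco, split, arrays = _load_arrays(data_dir)
    test_ids = list(split.test_ids)
    repeat_idx = config.repeats if config.repeats is not None else list(range(len(split.repeats)))

    phase_imgs = _phase_images(arrays) if config.image_version in ("slim", "translated") else None
    masks = {i: a["mask"] for i, a in arrays.items()}
    annotations = {i: a["boxes"] for i, a in arrays.items()}

    for r in repeat_idx:
        rep = split.repeats[r]
        train_ids, val_ids = list(rep["train_ids"]), list(rep["val_ids"])
        rep_dir = out / f"rep{r}"
        (rep_dir / "masks").mkdir(parents=True, exist_ok=True)
        (rep_dir / "fused").mkdir(exist_ok=True)

        # ---- stage inputs for this repeat --------------------------------
        if config.image_version == "brightfield":
            images = {i: arrays[i]["bf"] for i in arrays}
        elif config.image_version == "slim":
            images = {i: _to_rgb(phase_imgs[i]) for i in arrays}
        else:  # translated: train the cGAN on this repeat's split first
            tcfg = replace(config.translator, seed=_substream_seed(config.seed, "translate", r))
            pairs = {i: (phase_imgs[i], arrays[i]["bf"]) for i in arrays}
            keys = list(pairs)
            gen, tres = train_translator(
                [pairs[i] for i in keys],
                [keys.index(i) for i in train_ids],
                [keys.index(i) for i in val_ids],
                tcfg,
            )
            _write_log(rep_dir / "translate_log.csv", tres)
            images = {
                i: translate(gen, phase_imgs[i], input_size=tcfg.input_size) for i in arrays
            }

        # ---- detector ----------------------------------------------------
        dcfg = replace(config.detector, seed=_substream_seed(config.seed, "detect", r))
        det_model, dres = train_detector(images, annotations, train_ids, val_ids, dcfg)
        _write_log(rep_dir / "detect_log.csv", dres)

        # ---- segmenter ---------------------------------------------------
        scfg = replace(config.segmenter, seed=_substream_seed(config.seed, "segment", r))
        seg_model, sres = train_segmenter(images, masks, train_ids, val_ids, scfg)
        _write_log(rep_dir / "segment_log.csv", sres)

        # ---- test-set inference + fusion ---------------------------------
        import imageio.v3 as iio

        det_records = []
        for i in test_ids:
            dets = detect(det_model, images[i], config.score_threshold, config.nms_iou)
            for d in dets:
                x0, y0, x1, y1 = d.box
                det_records.append(
                    {"image_id": i, "category_id": d.wbc_class,
                     "bbox": [x0, y0, x1 - x0, y1 - y0], "score": d.confidence}
                )
            mask = segment(seg_model, images[i], config.segmenter.binarize_threshold)
            iio.imwrite(rep_dir / "masks" / f"{i:05d}.png", mask * 255)
            fused = fusion.fuse(mask, dets)
            iio.imwrite(rep_dir / "fused" / f"{i:05d}.png", fused)
        (rep_dir / "detections.json").write_text(json.dumps(det_records))
        (rep_dir / "val_metrics.json").write_text(
            json.dumps({"best_epoch_detect": dres.best_epoch, "best_val_mAP": dres.best_val,
                        "best_epoch_segment": sres.best_epoch, "best_val_mse": sres.best_val})
        )

    report = compile_report(Path(config.out_dir), data_dir, config.image_version, repeat_idx)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "report.md").write_text(report.to_markdown())
    return report


def _write_log(path: Path, result) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss"])
        for rec in result.log:
            writer.writerow([rec.epoch, rec.train_metric, rec.val_metric])


def compile_report(out_dir: Path, data_dir: Path, image_version: str,
                   repeat_idx: list[int] | None = None) -> RunReport:
    """Recompute the run report from persisted per-stage artifacts.

    Pure function of what is on disk: per-repeat detections and fused maps
    are re-scored against the dataset ground truth, and the voting row is
    recomputed from exactly the per-repeat maps listed.
    """
    import imageio.v3 as iio

    data_dir = Path(data_dir)
    version_dir = Path(out_dir) / image_version
    coco, split, arrays = _load_arrays(data_dir)
    test_ids = list(split.test_ids)
    if repeat_idx is None:
        repeat_idx = sorted(
            int(p.name[3:]) for p in version_dir.glob("rep*") if p.is_dir()
        )
    gt_boxes = [(i, b, c) for i in test_ids for b, c in arrays[i]["boxes"]]

    per_repeat = []
    fused_by_repeat: dict[int, dict[int, np.ndarray]] = {}
    for r in repeat_idx:
        rep_dir = version_dir / f"rep{r}"
        dets_json = json.loads((rep_dir / "detections.json").read_text())
        dets = [
            (d["image_id"],
             (d["bbox"][0], d["bbox"][1], d["bbox"][0] + d["bbox"][2], d["bbox"][1] + d["bbox"][3]),
             d["category_id"], d["score"])
            for d in dets_json
        ]
        det_eval = metrics.evaluate_detections(dets, gt_boxes)
        fused_by_repeat[r] = {
            i: iio.imread(rep_dir / "fused" / f"{i:05d}.png") for i in test_ids
        }
        f1s = _semantic_scores(fused_by_repeat[r], arrays, test_ids)
        per_repeat.append(
            {"repeat": r, "mAP": det_eval["mAP"],
             "per_class_ap": {k: v for k, v in det_eval["per_class_ap"].items()},
             "macro_f1": f1s["macro_f1"], "per_class_f1": f1s["per_class_f1"]}
        )

    voted = {
        i: fusion.majority_vote([fused_by_repeat[r][i] for r in repeat_idx]) for i in test_ids
    }
    voting = _semantic_scores(voted, arrays, test_ids)

    map_mean, map_std = metrics.aggregate([p["mAP"] for p in per_repeat])
    f1_mean, f1_std = metrics.aggregate([p["macro_f1"] for p in per_repeat])
    return RunReport(
        image_version=image_version,
        per_repeat=per_repeat,
        aggregate={"mAP": {"mean": map_mean, "std": map_std},
                   "macro_f1": {"mean": f1_mean, "std": f1_std}},
        voting=voting,
    )


def _semantic_scores(pred_maps: dict[int, np.ndarray], arrays, test_ids) -> dict:
    """Pixel scores pooled over the test set (one confusion per class)."""
    pred = np.concatenate([pred_maps[i].ravel() for i in test_ids])
    gt = np.concatenate([arrays[i]["sem"].ravel() for i in test_ids])
    scores = metrics.pixel_scores(pred, gt)
    return {
        "per_class_f1": {int(k): float(v) for k, v in scores.f1.items()},
        "macro_f1": metrics.macro_f1(scores),
    }


def compare_versions(config: RunConfig) -> dict[str, RunReport]:
    """Run all three image versions on identical splits and seeds."""
    reports = {}
    for version in VERSIONS:
        cfg = replace(config, image_version=version)
        reports[version] = run_pipeline(cfg)
    return reports
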