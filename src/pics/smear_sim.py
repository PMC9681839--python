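"""Synthetic Wright-stained blood-smear fields with full ground truth.

Each simulated field contains a red-blood-cell background and a small number
of white blood cells from four classes, rendered jointly as

* a ground-truth optical-pathlength (phase) map — nuclei retard light more
  than cytoplasm, cytoplasm more than background,
* an 8-bit RGB brightfield rendering with Wright-stain color conventions
  (purple nuclei, red eosinophil granules, pale pink RBCs),
* a four-frame interferogram stack produced by the phase-shifting forward
  model (with optional halo shading and intensity noise),
* ground-truth bounding boxes, a binary WBC mask and a semantic label map.

The morphology rules are deliberately schematic: neutrophils get 3–5 nuclear
lobes, eosinophils a bilobed nucleus plus red granular cytoplasm, lymphocytes
a large round nucleus with a thin cytoplasm rim, monocytes a kidney-shaped
nucleus and the largest body.  Sizes follow hematology convention
(lymphocyte 8–10 µm, neutrophil/eosinophil 10–14 µm, monocyte 14–18 µm).
The classes are therefore separable by size, color and texture — which is
all the downstream detector/segmenter contracts require — without any claim
of photometric realism.

Class priors default to the midpoints of the normal differential ranges
(neutrophils 40–60 %, lymphocytes 20–40 %, monocytes 2–8 %, eosinophils
1–4 %), renormalized.  Basophils are not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from pics.slim_recon import InterferogramStack, PhaseMap

__all__ = [
    "SmearConfig",
    "SmearSample",
    "DatasetSplit",
    "DEFAULT_CLASS_PRIORS",
    "CLASS_NAMES",
    "sample_class_counts",
    "render_smear",
    "forward_interferograms",
    "make_splits",
    "make_dataset",
    "load_dataset",
]

CLASS_NAMES = {1: "neutrophil", 2: "eosinophil", 3: "lymphocyte", 4: "monocyte"}

# midpoints of the normal WBC differential ranges, renormalized to sum to 1
_RAW_MIDPOINTS = np.array([0.50, 0.025, 0.30, 0.05])
DEFAULT_CLASS_PRIORS = tuple(_RAW_MIDPOINTS / _RAW_MIDPOINTS.sum())

# cell diameters in micrometres: (lo, hi) per class id
_DIAMETER_UM = {1: (10.0, 14.0), 2: (10.0, 14.0), 3: (8.0, 10.0), 4: (14.0, 18.0)}
_RBC_DIAMETER_UM = (6.5, 8.0)

# Wright-stain palette (RGB in [0, 1])
_BACKGROUND_RGB = np.array([0.93, 0.92, 0.94])
_RBC_RGB = np.array([0.90, 0.71, 0.69])
_CYTO_RGB = {
    1: np.array([0.85, 0.78, 0.88]),  # pale lilac
    2: np.array([0.89, 0.74, 0.70]),  # pinkish, carries red granules
    3: np.array([0.62, 0.70, 0.88]),  # thin blue rim
    4: np.array([0.72, 0.78, 0.86]),  # gray-blue
}
_NUCLEUS_RGB = {
    1: np.array([0.38, 0.24, 0.58]),
    2: np.array([0.42, 0.26, 0.58]),
    3: np.array([0.30, 0.18, 0.52]),
    4: np.array([0.47, 0.33, 0.63]),
}
_GRANULE_RGB = np.array([0.78, 0.22, 0.28])

# phase levels in radians (pre-smoothing)
_PHASE_CYTO = {1: 0.9, 2: 0.95, 3: 0.85, 4: 0.8}
_PHASE_NUCLEUS = {1: 1.9, 2: 1.8, 3: 2.0, 4: 1.7}
_PHASE_RBC = 0.7


class ConfigError(ValueError):
    """Invalid simulator configuration."""


class GenerationError(RuntimeError):
    """A field could not be populated at the requested density."""


@dataclass(frozen=True)
class SmearConfig:
    """Simulation conditions for one smear field.

    ``wbc_density`` is the mean of a Poisson count truncated at >= 1 (blood
    smear fields are selected to contain at least one leukocyte);
    ``rbc_density`` is a plain Poisson mean.  ``halo_strength`` in [0, 1]
    subtracts that fraction of the low-pass phase before interference,
    mimicking the high-pass halo shading of phase-contrast illumination.
    """

    field_size: tuple[int, int] = (256, 256)
    pixel_size: float = 0.4  # µm per pixel
    wbc_density: float = 2.0
    class_priors: tuple[float, ...] = DEFAULT_CLASS_PRIORS
    rbc_density: float = 40.0
    beta_background: float = 0.3
    noise_sigma: float = 0.01
    halo_strength: float = 0.25
    halo_sigma_px: float = 8.0
    seed: int = 0

    def __post_init__(self):
        priors = np.asarray(self.class_priors, dtype=float)
        if priors.shape != (4,) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-9:
            raise ConfigError(f"class_priors must be a 4-vector summing to 1, got {priors}")
        if self.wbc_density < 0 or self.rbc_density < 0:
            raise ConfigError("densities must be nonnegative")
        if not 0.0 <= self.halo_strength <= 1.0:
            raise ConfigError("halo_strength must lie in [0, 1]")
        if self.noise_sigma < 0 or self.beta_background < 0:
            raise ConfigError("noise_sigma and beta_background must be nonnegative")


@dataclass
class GroundTruthBox:
    """Axis-aligned box (x_min, y_min, x_max, y_max), half-open, with class."""

    box: tuple[float, float, float, float]
    wbc_class: int
    confidence: float = 1.0


@dataclass
class SmearSample:
    phase_gt: PhaseMap
    brightfield: np.ndarray  # (H, W, 3) uint8
    stack: InterferogramStack
    boxes: list[GroundTruthBox]
    binary_mask: np.ndarray  # (H, W) uint8 in {0, 1}
    semantic_gt: np.ndarray  # (H, W) uint8 in {0..4}


@dataclass
class DatasetSplit:
    """Fixed test set plus R repeated train/val partitions of the remainder."""

    test_ids: list[int]
    repeats: list[dict]  # each {"train_ids": [...], "val_ids": [...]}
    seed: int

    def validate(self) -> None:
        test = set(self.test_ids)
        for rep in self.repeats:
            train, val = set(rep["train_ids"]), set(rep["val_ids"])
            if train & val or test & (train | val):
                raise ValueError("split partitions overlap")


def sample_class_counts(
    n_cells: int, priors, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial draw of per-class WBC counts (order: classes 1..4)."""
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (4,) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-9:
        raise ConfigError(f"invalid priors {priors}")
    if n_cells < 0:
        raise ConfigError("n_cells must be >= 0")
    return rng.multinomial(n_cells, priors)


# --------------------------------------------------------------------------
# geometry helpers


def _ellipse_mask(h, w, cy, cx, ry, rx, angle):
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _nucleus_mask(cls, h, w, cy, cx, r, angle, rng):
    if cls == 1:  # neutrophil: 3-5 lobes
        n_lobes = int(rng.integers(3, 6))
        mask = np.zeros((h, w), bool)
        base = rng.uniform(0, 2 * np.pi)
        for i in range(n_lobes):
            th = base + 2 * np.pi * i / n_lobes + rng.normal(0, 0.2)
            ly, lx = cy + 0.38 * r * np.sin(th), cx + 0.38 * r * np.cos(th)
            lr = r * rng.uniform(0.24, 0.32)
            mask |= _ellipse_mask(h, w, ly, lx, lr, lr * rng.uniform(0.8, 1.2), th)
        return mask
    if cls == 2:  # eosinophil: bilobed
        mask = np.zeros((h, w), bool)
        for sgn in (-1, 1):
            ly = cy + sgn * 0.33 * r * np.sin(angle)
            lx = cx + sgn * 0.33 * r * np.cos(angle)
            lr = r * rng.uniform(0.30, 0.38)
            mask |= _ellipse_mask(h, w, ly, lx, lr, lr, angle)
        return mask
    if cls == 3:  # lymphocyte: large round nucleus
        nr = r * rng.uniform(0.72, 0.82)
        return _ellipse_mask(h, w, cy, cx, nr, nr, 0.0)
    # monocyte: kidney = big ellipse minus offset bite
    nr = r * rng.uniform(0.60, 0.70)
    body = _ellipse_mask(h, w, cy, cx, nr, nr * rng.uniform(0.85, 1.0), angle)
    by = cy + 0.55 * nr * np.sin(angle + np.pi / 2)
    bx = cx + 0.55 * nr * np.cos(angle + np.pi / 2)
    bite = _ellipse_mask(h, w, by, bx, 0.55 * nr, 0.55 * nr, angle)
    return body & ~bite


def _truncated_poisson_ge1(mean: float, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    for _ in range(1000):
        n = int(rng.poisson(mean))
        if n >= 1:
            return n
    return 1


# --------------------------------------------------------------------------
# rendering


def render_smear(config: SmearConfig, rng: np.random.Generator | None = None) -> SmearSample:
    """Render one fully annotated smear field.

    WBCs are placed by rejection sampling so that their bounding squares do
    not overlap (hence ground-truth boxes are disjoint and every foreground
    component lies in exactly one box); WBC–RBC overlap is allowed and RBCs
    are drawn underneath.  If a drawn cell census cannot be placed, the field
    layout is resampled a bounded number of times before a
    :class:`GenerationError` is raised.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h, w = config.field_size
    px = config.pixel_size

    n_wbc = _truncated_poisson_ge1(config.wbc_density, rng)
    counts = sample_class_counts(n_wbc, config.class_priors, rng)
    classes = [c + 1 for c in range(4) for _ in range(counts[c])]
    rng.shuffle(classes)

    for _attempt in range(10):
        placed = _try_place(classes, h, w, px, rng)
        if placed is not None:
            break
    else:
        raise GenerationError(
            f"could not place {len(classes)} WBCs of classes {classes} in a "
            f"{h}x{w} field at {px} µm/px after bounded retries"
        )

    phase = np.zeros((h, w), np.float64)
    bf = np.empty((h, w, 3), np.float64)
    bf[:] = _BACKGROUND_RGB
    bf += rng.normal(0, 0.012, (h, w, 3))
    semantic = np.zeros((h, w), np.uint8)

    # RBC background (drawn first, underneath)
    n_rbc = int(rng.poisson(config.rbc_density))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_rbc):
        d = rng.uniform(*_RBC_DIAMETER_UM) / px
        r = d / 2
        cy, cx = rng.uniform(-r, h + r), rng.uniform(-r, w + r)
        rr2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
        disc = rr2 <= 1.0
        if not disc.any():
            continue
        # biconcave: pale centre, denser rim
        profile = 0.45 + 0.55 * rr2[disc]
        phase[disc] = np.maximum(phase[disc], _PHASE_RBC * profile)
        tint = _RBC_RGB + 0.12 * (1.0 - profile[:, None])
        bf[disc] = 0.25 * bf[disc] + 0.75 * tint

    boxes: list[GroundTruthBox] = []
    for cls, (cy, cx, r) in placed:
        angle = rng.uniform(0, np.pi)
        ecc = rng.uniform(0.85, 1.0)
        body = _ellipse_mask(h, w, cy, cx, r, r * ecc, angle)
        nucleus = _nucleus_mask(cls, h, w, cy, cx, r, angle, rng) & body
        cyto = body & ~nucleus

        bf[cyto] = _CYTO_RGB[cls] + rng.normal(0, 0.02, 3)
        if cls == 2:  # red granules speckled over the cytoplasm
            speckle = cyto & (rng.random((h, w)) < 0.45)
            bf[speckle] = _GRANULE_RGB + rng.normal(0, 0.03, 3)
        bf[nucleus] = _NUCLEUS_RGB[cls] + rng.normal(0, 0.02, 3)

        phase[cyto] = _PHASE_CYTO[cls] * rng.uniform(0.9, 1.1)
        phase[nucleus] = _PHASE_NUCLEUS[cls] * rng.uniform(0.9, 1.1)

        semantic[body] = cls
        ys, xs = np.nonzero(body)
        boxes.append(
            GroundTruthBox(
                box=(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)),
                wbc_class=cls,
            )
        )

    binary = (semantic > 0).astype(np.uint8)

    # gentle smoothing inside the phase only (labels stay crisp)
    phase = ndimage.gaussian_filter(phase, 0.8)
    phase += ndimage.gaussian_filter(rng.normal(0, 0.05, (h, w)), 3.0)
    phase = np.clip(phase, 0.0, np.pi)

    bf8 = np.clip(bf, 0.0, 1.0)
    bf8 = (bf8 * 255).round().astype(np.uint8)

    transmission = bf8.astype(np.float64) / 255.0
    stack = forward_interferograms(
        PhaseMap(phase, provenance="simulated", pixel_size=px),
        beta=config.beta_background,
        noise_sigma=config.noise_sigma,
        halo_strength=config.halo_strength,
        rng=rng,
        halo_sigma_px=config.halo_sigma_px,
        transmission=transmission,
    )
    return SmearSample(
        phase_gt=PhaseMap(phase, provenance="simulated", pixel_size=px),
        brightfield=bf8,
        stack=stack,
        boxes=boxes,
        binary_mask=binary,
        semantic_gt=semantic,
    )


def _try_place(classes, h, w, px, rng, per_cell_tries: int = 80):
    """Sample non-overlapping (bounding-square-disjoint) centres; None on failure.

    Largest cells are placed first; when rejection sampling dead-ends, a
    shuffled grid scan finds a feasible centre if one exists at all.
    Returns ``[(class, (cy, cx, r)), ...]`` or None.
    """
    radii = [rng.uniform(*_DIAMETER_UM[cls]) / px / 2 for cls in classes]
    order = sorted(range(len(classes)), key=lambda i: -radii[i])
    placed: list[tuple[float, float, float]] = []
    out = []
    for i in order:
        cls, r = classes[i], radii[i]
        lo_y, hi_y = r + 1, h - r - 1
        lo_x, hi_x = r + 1, w - r - 1
        if hi_y <= lo_y or hi_x <= lo_x:
            return None

        def ok(cy, cx):
            return all(max(abs(cy - py), abs(cx - qx)) > r + pr + 2.0 for py, qx, pr in placed)

        centre = None
        for _ in range(per_cell_tries):
            cy, cx = rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)
            if ok(cy, cx):
                centre = (cy, cx)
                break
        if centre is None:  # systematic fallback on a jittered 2-px grid
            cand = [(cy, cx) for cy in np.arange(lo_y, hi_y, 2.0) for cx in np.arange(lo_x, hi_x, 2.0)]
            rng.shuffle(cand)
            centre = next(((cy, cx) for cy, cx in cand if ok(cy, cx)), None)
            if centre is None:
                return None
        placed.append((*centre, r))
        out.append((cls, (*centre, r)))
    return out


def forward_interferograms(
    phase_gt: PhaseMap | np.ndarray,
    beta,
    noise_sigma: float = 0.0,
    halo_strength: float = 0.0,
    rng: np.random.Generator | None = None,
    halo_sigma_px: float = 8.0,
    transmission: np.ndarray | None = None,
) -> InterferogramStack:
    """Phase-shifting forward model: four frames at delays k*pi/2.

    ``I_k = T * (1 + beta^2 + 2 beta cos(phi_eff + k pi/2)) + eps_k`` with
    ``phi_eff = phi - halo_strength * lowpass(phi)`` (Gaussian low-pass of
    width ``halo_sigma_px``) and ``eps_k ~ N(0, noise_sigma^2)`` clipped so
    intensities stay nonnegative.  ``transmission`` (optional, per-channel)
    models stain absorption seen by a color camera; omit it for the plain
    grayscale forward model.  The phase entering this model is the
    incident-vs-scattered difference recovered by the four-bucket inversion.
    """
    phi = phase_gt.phi if isinstance(phase_gt, PhaseMap) else np.asarray(phase_gt, float)
    pixel_size = phase_gt.pixel_size if isinstance(phase_gt, PhaseMap) else 1.0
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be nonnegative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    phi_eff = phi
    if halo_strength:
        phi_eff = phi - halo_strength * ndimage.gaussian_filter(phi, halo_sigma_px)
    frames = []
    for k in range(4):
        intensity = 1.0 + beta**2 + 2.0 * beta * np.cos(phi_eff + k * np.pi / 2.0)
        if transmission is not None:
            intensity = transmission * intensity[..., None]
        if noise_sigma > 0:
            if rng is None:
                raise ValueError("rng required when noise_sigma > 0")
            intensity = intensity + rng.normal(0, noise_sigma, intensity.shape)
        frames.append(np.clip(intensity, 0.0, None))
    return InterferogramStack(np.stack(frames), pixel_size=pixel_size)


# --------------------------------------------------------------------------
# dataset assembly


def make_splits(
    n_images: int,
    n_test: int,
    train_val_ratio: float = 8.0,
    n_repeats: int = 5,
    seed: int = 0,
) -> DatasetSplit:
    """Hold out a fixed test set, then partition the rest R times at the ratio.

    ``val = floor(remaining / (1 + ratio))``, train takes the remainder; with
    504 images, 50 test and an 8:1 ratio this gives 404 train / 50 val.
    """
    if not 0 <= n_test < n_images:
        raise ConfigError("need 0 <= n_test < n_images")
    if train_val_ratio <= 0:
        raise ConfigError("train_val_ratio must be positive")
    rng = np.random.default_rng(seed)
    ids = np.arange(n_images)
    perm = rng.permutation(ids)
    test_ids = sorted(int(i) for i in perm[:n_test])
    rest = np.array(sorted(int(i) for i in perm[n_test:]))
    n_val = int(len(rest) // (1.0 + train_val_ratio))
    repeats = []
    for _ in range(n_repeats):
        p = rng.permutation(rest)
        repeats.append(
            {
                "val_ids": sorted(int(i) for i in p[:n_val]),
                "train_ids": sorted(int(i) for i in p[n_val:]),
            }
        )
    split = DatasetSplit(test_ids=test_ids, repeats=repeats, seed=seed)
    split.validate()
    return split


def make_dataset(
    out_dir: str | Path,
    n_images: int = 504,
    n_test: int = 50,
    train_val_ratio: float = 8.0,
    n_repeats: int = 5,
    config: SmearConfig | None = None,
    seed: int = 0,
    force: bool = False,
) -> DatasetSplit:
    """Render ``n_images`` fields to disk with COCO-style annotations.

    Per sample: ``<id>_phase.tif`` (float32 radians), ``<id>_bf.png`` (8-bit
    RGB), ``<id>_s{0..3}.tif`` (float32 interferograms), ``<id>_mask.png``
    (0/255), ``<id>_sem.png`` (labels 0–4).  Dataset level:
    ``annotations.json`` (images / categories 1–4 / bounding boxes
    [x, y, width, height], iscrowd=0) and ``splits.json``.
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty; pass force=True")
    out.mkdir(parents=True, exist_ok=True)
    config = config or SmearConfig()

    rng = np.random.default_rng(seed)
    images, annotations = [], []
    ann_id = 1
    for img_id in range(n_images):
        sample = render_smear(config, np.random.default_rng(rng.integers(0, 2**31)))
        sid = f"{img_id:05d}"
        tifffile.imwrite(out / f"{sid}_phase.tif", sample.phase_gt.phi.astype(np.float32))
        iio.imwrite(out / f"{sid}_bf.png", sample.brightfield)
        for k in range(4):
            frame = sample.stack.frames[k].astype(np.float32)
            photometric = "rgb" if frame.ndim == 3 else "minisblack"
            tifffile.imwrite(out / f"{sid}_s{k}.tif", frame, photometric=photometric)
        iio.imwrite(out / f"{sid}_mask.png", (sample.binary_mask * 255).astype(np.uint8))
        iio.imwrite(out / f"{sid}_sem.png", sample.semantic_gt)
        h, w = sample.semantic_gt.shape
        images.append({"id": img_id, "file_name": f"{sid}_bf.png", "width": w, "height": h})
        for b in sample.boxes:
            x0, y0, x1, y1 = b.box
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": b.wbc_class,
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    coco = {
        "images": images,
        "categories": [{"id": k, "name": v} for k, v in CLASS_NAMES.items()],
        "annotations": annotations,
    }
    (out / "annotations.json").write_text(json.dumps(coco))
    split = make_splits(n_images, n_test, train_val_ratio, n_repeats, seed)
    (out / "splits.json").write_text(
        json.dumps({"test_ids": split.test_ids, "repeats": split.repeats, "seed": seed})
    )
    return split


def load_dataset(data_dir: str | Path):
    """Load annotations and split from a dataset directory.

    Returns ``(coco_dict, DatasetSplit)``; images are loaded lazily by id via
    the file-name patterns written by :func:`make_dataset`.
    """
    data = Path(data_dir)
    coco = json.loads((data / "annotations.json").read_text())
    s = json.loads((data / "splits.json").read_text())
    split = DatasetSplit(test_ids=s["test_ids"], repeats=s["repeats"], seed=s["seed"])
    split.validate()
    return coco, split
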