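"""Synthetic IHC patch simulator and dataset plumbing.

Patches emulate hematoxylin-counterstained tissue with DAB-positive
structures (CD34-like vessels are approximated as disks or ribbon-shaped
random walks; morphological realism is not the goal, statistical control
is).  Per-pixel stain concentrations are rendered to RGB through the
Lambert-Beer law with the published hematoxylin/DAB stain vectors, so the
deconvolution module can recover the generating concentrations exactly in
the noise-free case.

Labels follow the semi-quantitative IHC convention: a staining-intensity
score (0-3, from the mean DAB optical density) plus a positive-proportion
score (0-4, from the stained area fraction); their sum maps to the four
classes negative / weak positive / positive / strong positive.

Also provided: grid patchify with background screening, stratified 7:3
train/validation splitting (floor on the training side), and deterministic
label-preserving augmentation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.transform import resize

from .stains import (
    DEFAULT_INCIDENT_INTENSITY,
    HD_RAW,
    complete_two_stain_matrix,
    rgb_to_od,
)

__all__ = [
    "CLASS_NAMES",
    "ScoreThresholds",
    "SceneSpec",
    "PatchTruth",
    "PatchRecord",
    "SplitManifest",
    "DEFAULT_CLASS_SPECS",
    "score_patch",
    "render_patch",
    "generate_dataset",
    "table1_counts",
    "patchify_and_screen",
    "split_dataset",
    "augment",
    "records_to_manifest",
    "write_dataset",
    "load_dataset",
]

CLASS_NAMES = ("negative", "weak_positive", "positive", "strong_positive")


class ConfigError(ValueError):
    """Invalid scoring thresholds or class specification."""


@dataclass(frozen=True)
class ScoreThresholds:
    """Bin edges for the semi-quantitative score and the class cut points.

    ``intensity_edges`` split mean DAB OD into scores 0-3 (score = number of
    edges at or below the value); ``proportion_edges`` split the stained
    area fraction into scores 0-4.  ``class_cuts`` are the lowest total
    score of weak_positive / positive / strong_positive.
    """

    intensity_edges: tuple[float, ...] = (0.15, 0.4, 0.8)
    proportion_edges: tuple[float, ...] = (0.01, 0.1, 0.33, 0.66)
    class_cuts: tuple[int, int, int] = (1, 4, 6)

    def __post_init__(self) -> None:
        for name, edges in (
            ("intensity_edges", self.intensity_edges),
            ("proportion_edges", self.proportion_edges),
            ("class_cuts", self.class_cuts),
        ):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ConfigError(f"{name} must be strictly increasing: {edges}")
        if min(self.intensity_edges) <= 0 or min(self.proportion_edges) <= 0:
            raise ConfigError("score edges must be positive (0 is the implicit floor)")


DEFAULT_THRESHOLDS = ScoreThresholds()


def score_patch(
    dab_mean_od: float,
    dab_area_fraction: float,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> tuple[int, int, str]:
    """Semi-quantitative score: (intensity 0-3, proportion 0-4, class label)."""
    if dab_mean_od < 0 or not 0 <= dab_area_fraction <= 1:
        raise ValueError("dab_mean_od must be >= 0 and area fraction in [0, 1]")
    intensity = int(np.searchsorted(thresholds.intensity_edges, dab_mean_od, side="right"))
    proportion = int(
        np.searchsorted(thresholds.proportion_edges, dab_area_fraction, side="right")
    )
    total = intensity + proportion
    cuts = thresholds.class_cuts
    if total < cuts[0]:
        label = CLASS_NAMES[0]
    elif total < cuts[1]:
        label = CLASS_NAMES[1]
    elif total < cuts[2]:
        label = CLASS_NAMES[2]
    else:
        label = CLASS_NAMES[3]
    return intensity, proportion, label


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic patch scene.

    ``dab_mean_od`` is the DAB concentration (in units of the unit-norm DAB
    OD vector) inside the stained structures; ``dab_area_fraction`` the
    target fraction of stained pixels.  ``stain_jitter_sd`` perturbs the
    stain vectors per patch (slide-to-slide stain variation) and
    ``noise_sd`` adds Gaussian pixel noise in grey levels.
    """

    patch_size: int = 256
    n_nuclei: int | None = None
    nucleus_radius_range: tuple[float, float] | None = None
    dab_area_fraction: float = 0.0
    dab_mean_od: float = 0.0
    dab_shape: str = "disks"
    stain_jitter_sd: float = 0.02
    noise_sd: float = 2.0
    hematoxylin_od_range: tuple[float, float] = (0.35, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dab_area_fraction <= 1.0:
            raise ConfigError("dab_area_fraction must be in [0, 1]")
        if self.dab_mean_od < 0 or self.stain_jitter_sd < 0 or self.noise_sd < 0:
            raise ConfigError("intensities and noise levels must be nonnegative")
        if self.dab_shape not in ("disks", "vessel_ribbons"):
            raise ConfigError(f"unknown dab_shape {self.dab_shape!r}")

    @property
    def resolved_nucleus_radii(self) -> tuple[float, float]:
        if self.nucleus_radius_range is not None:
            return self.nucleus_radius_range
        scale = self.patch_size / 256
        return (max(1.5, 4 * scale), max(2.5, 9 * scale))

    @property
    def resolved_n_nuclei(self) -> int:
        if self.n_nuclei is not None:
            return self.n_nuclei
        # aim for ~22% nuclear coverage regardless of patch scale
        r_lo, r_hi = self.resolved_nucleus_radii
        r_mean = 0.5 * (r_lo + r_hi)
        return max(4, round(0.22 * self.patch_size**2 / (np.pi * r_mean**2)))


@dataclass(frozen=True)
class PatchTruth:
    intensity_score: int
    proportion_score: int
    dab_area_fraction: float
    dab_mean_od: float


@dataclass
class PatchRecord:
    """A rendered patch with its label and generator ground truth."""

    id: str
    image: np.ndarray
    label: str
    truth: PatchTruth
    seed: int
    dab_mask: np.ndarray | None = None
    path: str | None = None
    split: str | None = None


@dataclass(frozen=True)
class SplitManifest:
    train: tuple[str, ...]
    val: tuple[str, ...]
    ratio: tuple[int, int]
    seed: int
    stratified: bool


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_HD_MATRIX = complete_two_stain_matrix(HD_RAW)
_H_VEC = _HD_MATRIX.matrix[0]
_D_VEC = _HD_MATRIX.matrix[1]


def _jitter_vec(vec: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return vec
    v = np.clip(vec + rng.normal(0.0, sd, size=3), 1e-6, None)
    return v / np.linalg.norm(v)


def _dab_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Grow a DAB support mask until the target area fraction is reached."""
    size = spec.patch_size
    mask = np.zeros((size, size), dtype=bool)
    target = spec.dab_area_fraction
    if target <= 0:
        return mask
    r_lo = max(2.0, 0.02 * size)
    r_hi = max(r_lo + 1.0, 0.06 * size)
    for _ in range(10_000):
        if mask.mean() >= target:
            break
        if spec.dab_shape == "disks":
            center = rng.uniform(0, size, size=2)
            radius = rng.uniform(r_lo, r_hi)
            rr, cc = draw_disk(center, radius, shape=mask.shape)
            mask[rr, cc] = True
        else:  # vessel_ribbons: a widened random walk
            pos = rng.uniform(0.1 * size, 0.9 * size, size=2)
            angle = rng.uniform(0, 2 * np.pi)
            width = rng.uniform(r_lo / 2, r_hi / 2)
            path = np.zeros_like(mask)
            for _step in range(rng.integers(4, 10)):
                angle += rng.normal(0.0, 0.6)
                step = rng.uniform(0.05, 0.12) * size
                nxt = pos + step * np.array([np.sin(angle), np.cos(angle)])
                nxt = np.clip(nxt, 0, size - 1)
                rr, cc = draw_line(*np.round(pos).astype(int), *np.round(nxt).astype(int))
                path[rr, cc] = True
                pos = nxt
            from scipy.ndimage import binary_dilation

            yy, xx = np.ogrid[-int(width) : int(width) + 1, -int(width) : int(width) + 1]
            footprint = yy**2 + xx**2 <= width**2
            mask |= binary_dilation(path, structure=footprint)
    return mask


def render_patch(spec: SceneSpec, quantize: bool = True) -> PatchRecord:
    """Render one patch through the Lambert-Beer forward model.

    Per-pixel hematoxylin and DAB concentrations are mapped to optical
    density via the unit-norm stain vectors, then to transmitted RGB as
    ``I = I_0 * 10**(-OD)``.  With ``quantize=False`` the image stays a
    float array (no 8-bit rounding) so unmixing is exact.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.patch_size
    c_hem = np.zeros((size, size))
    c_dab = np.zeros((size, size))

    # hematoxylin-stained nuclei: overlapping disks, max-composited
    r_lo, r_hi = spec.resolved_nucleus_radii
    od_lo, od_hi = spec.hematoxylin_od_range
    for _ in range(spec.resolved_n_nuclei):
        center = rng.uniform(0, size, size=2)
        radius = rng.uniform(r_lo, r_hi)
        level = rng.uniform(od_lo, od_hi)
        rr, cc = draw_disk(center, radius, shape=c_hem.shape)
        np.maximum.at(c_hem, (rr, cc), level)

    mask = _dab_mask(spec, rng)
    if mask.any():
        c_dab[mask] = spec.dab_mean_od
    achieved_fraction = float(mask.mean())
    achieved_od = spec.dab_mean_od if mask.any() else 0.0

    h_vec = _jitter_vec(_H_VEC, spec.stain_jitter_sd, rng)
    d_vec = _jitter_vec(_D_VEC, spec.stain_jitter_sd, rng)
    od = c_hem[..., None] * h_vec + c_dab[..., None] * d_vec
    intensity = DEFAULT_INCIDENT_INTENSITY * np.power(10.0, -od)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    if quantize:
        image = np.clip(np.floor(intensity + 0.5), 0, 255).astype(np.uint8)
    else:
        image = np.clip(intensity, 1.0, 255.0)

    i_score, p_score, label = score_patch(achieved_od, achieved_fraction)
    truth = PatchTruth(i_score, p_score, achieved_fraction, achieved_od)
    return PatchRecord(
        id=f"patch-{spec.seed:010d}",
        image=image,
        label=label,
        truth=truth,
        seed=spec.seed,
        dab_mask=mask,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

#: per-class sampling ranges for (DAB mean OD, DAB area fraction); chosen to
#: land comfortably inside the default score bins so the rendered truth can
#: never cross a class boundary through area-overshoot
DEFAULT_CLASS_SPECS: dict[str, dict[str, tuple[float, float]]] = {
    "negative": {"od_range": (0.0, 0.0), "area_range": (0.0, 0.0)},
    "weak_positive": {"od_range": (0.2, 0.35), "area_range": (0.03, 0.08)},
    "positive": {"od_range": (0.45, 0.7), "area_range": (0.12, 0.28)},
    "strong_positive": {"od_range": (0.85, 1.15), "area_range": (0.4, 0.55)},
}


def _validate_class_specs(class_specs: dict) -> None:
    for label, spec in class_specs.items():
        if label not in CLASS_NAMES:
            raise ConfigError(f"unknown class {label!r}")
        od_lo, od_hi = spec["od_range"]
        ar_lo, ar_hi = spec["area_range"]
        if od_lo > od_hi or ar_lo > ar_hi or od_lo < 0 or ar_lo < 0 or ar_hi > 1:
            raise ConfigError(f"invalid ranges for class {label!r}")
        if label == "negative" and (od_hi > 0 or ar_hi > 0):
            raise ConfigError("negative class must have zero DAB intensity and area")
        if label != "negative" and (od_lo == 0 or ar_lo == 0):
            raise ConfigError(f"non-negative class {label!r} must have positive DAB")


def generate_dataset(
    n_per_class: dict[str, int],
    class_specs: dict | None = None,
    patch_size: int = 256,
    dab_shape: str = "disks",
    stain_jitter_sd: float = 0.02,
    noise_sd: float = 2.0,
    seed: int = 0,
    quantize: bool = True,
) -> list[PatchRecord]:
    """Generate labeled patches, exactly ``n_per_class[label]`` per class.

    Reproducible: the record list is a pure function of the arguments.  Each
    record's scene seed is drawn from one master generator seeded by
    ``seed``, so individual patches are independently re-renderable.
    """
    class_specs = dict(DEFAULT_CLASS_SPECS if class_specs is None else class_specs)
    _validate_class_specs(class_specs)
    for label in n_per_class:
        if label not in class_specs:
            raise ConfigError(f"no class spec for {label!r}")
        if n_per_class[label] < 0:
            raise ConfigError("counts must be nonnegative")
    master = np.random.default_rng(seed)
    records: list[PatchRecord] = []
    for label in CLASS_NAMES:
        count = n_per_class.get(label, 0)
        ranges = class_specs.get(label)
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * count:
                raise ConfigError(
                    f"class spec for {label!r} rarely yields that label; "
                    "its ranges disagree with the scoring bins"
                )
            od = master.uniform(*ranges["od_range"])
            area = master.uniform(*ranges["area_range"])
            scene = SceneSpec(
                patch_size=patch_size,
                dab_area_fraction=area,
                dab_mean_od=od,
                dab_shape=dab_shape,
                stain_jitter_sd=stain_jitter_sd,
                noise_sd=noise_sd,
                seed=int(master.integers(2**31)),
            )
            record = render_patch(scene, quantize=quantize)
            if record.label != label:
                continue  # boundary wobble; resample (rare by construction)
            record.id = f"{label}-{made:05d}-{record.seed:010d}"
            records.append(record)
            made += 1
    return records


def table1_counts(scale: float = 1.0) -> dict[str, int]:
    """Class counts with a realistic CD34-cohort imbalance.

    2437 / 606 / 773 / 742 patches for negative / weak / positive / strong
    (negatives dominate, as they do on real slides), scaled and rounded
    half-up.
    """
    base = dict(zip(CLASS_NAMES, (2437, 606, 773, 742)))
    return {k: int(np.floor(v * scale + 0.5)) for k, v in base.items()}


# ---------------------------------------------------------------------------
# patchify / screen / split / augment
# ---------------------------------------------------------------------------

def patchify_and_screen(
    slide_image: np.ndarray,
    patch_size: int = 256,
    tissue_fraction_min: float = 0.1,
    od_threshold: float = 0.15,
) -> tuple[list[tuple[np.ndarray, tuple[int, int]]], pd.DataFrame]:
    """Tile a slide into non-overlapping patches and screen out background.

    A pixel counts as tissue when its mean optical density over the three
    channels exceeds ``od_threshold``; a patch is kept when its tissue
    fraction reaches ``tissue_fraction_min``.  Returns the kept patches
    (with their grid position) and a log of every tile.
    """
    slide_image = np.asarray(slide_image)
    if slide_image.ndim != 3 or slide_image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 slide, got {slide_image.shape}")
    h, w = slide_image.shape[:2]
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds slide {h}x{w}")
    od = rgb_to_od(slide_image).od.mean(axis=2)
    tissue = od > od_threshold
    kept, rows = [], []
    for i in range(h // patch_size):
        for j in range(w // patch_size):
            sl = (
                slice(i * patch_size, (i + 1) * patch_size),
                slice(j * patch_size, (j + 1) * patch_size),
            )
            fraction = float(tissue[sl].mean())
            keep = fraction >= tissue_fraction_min
            rows.append({"row": i, "col": j, "tissue_fraction": fraction, "kept": keep})
            if keep:
                kept.append((slide_image[sl], (i, j)))
    return kept, pd.DataFrame(rows)


def split_dataset(
    records: list[PatchRecord],
    ratio: tuple[int, int] = (7, 3),
    stratified: bool = True,
    seed: int = 0,
) -> SplitManifest:
    """Shuffled train/validation split, floor(n * ratio) on the training side.

    Stratified per class by default (e.g. 2437 negatives -> 1705 / 732).
    Annotates each record's ``split`` field in place.
    """
    if not records:
        raise ValueError("no records to split")
    rng = np.random.default_rng(seed)
    frac = ratio[0] / (ratio[0] + ratio[1])
    groups: dict[str, list[PatchRecord]]
    if stratified:
        groups = {}
        for rec in records:
            groups.setdefault(rec.label, []).append(rec)
        for label, recs in groups.items():
            if not recs:
                raise ValueError(f"class {label!r} has no records; cannot stratify")
    else:
        groups = {"all": list(records)}
    train_ids: list[str] = []
    val_ids: list[str] = []
    for label in sorted(groups):
        recs = groups[label]
        order = rng.permutation(len(recs))
        n_train = int(np.floor(frac * len(recs)))
        for k, idx in enumerate(order):
            rec = recs[idx]
            rec.split = "train" if k < n_train else "val"
            (train_ids if k < n_train else val_ids).append(rec.id)
    return SplitManifest(
        train=tuple(train_ids),
        val=tuple(val_ids),
        ratio=ratio,
        seed=seed,
        stratified=stratified,
    )


def augment(
    patch: np.ndarray,
    ops: tuple[str, ...] = ("rotation", "crop", "color_jitter"),
    seed: int | np.random.Generator = 0,
    max_jitter: float = 0.045,
    crop_scale: tuple[float, float] = (0.8, 1.0),
) -> np.ndarray:
    """Label-preserving augmentation, deterministic under a fixed seed.

    Rotation picks a multiple of 90 degrees; crop takes a random sub-window
    and resizes back; color jitter applies per-channel multiplicative gains
    in ``[1 - max_jitter, 1 + max_jitter]``.  The default jitter bound keeps
    the effective DAB optical density shift below ~0.02, well inside the
    0.05 margin between the class-spec sampling ranges and the score-bin
    edges, so the semi-quantitative label cannot flip.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.asarray(patch)
    if out.ndim != 3 or out.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 patch, got {out.shape}")
    h, w = out.shape[:2]
    if "rotation" in ops:
        out = np.rot90(out, k=int(rng.integers(4)))
    if "crop" in ops:
        scale = rng.uniform(*crop_scale)
        ch, cw = max(1, round(scale * h)), max(1, round(scale * w))
        top = int(rng.integers(h - ch + 1))
        left = int(rng.integers(w - cw + 1))
        window = out[top : top + ch, left : left + cw]
        resized = resize(window.astype(float), (h, w, 3), preserve_range=True, anti_aliasing=True)
        out = np.clip(np.floor(resized + 0.5), 0, 255).astype(np.uint8)
    if "color_jitter" in ops:
        gains = rng.uniform(1.0 - max_jitter, 1.0 + max_jitter, size=3)
        out = np.clip(np.floor(out.astype(float) * gains + 0.5), 0, 255).astype(np.uint8)
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# manifests and disk IO
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "id",
    "path",
    "label",
    "intensity_score",
    "proportion_score",
    "dab_area_fraction",
    "dab_mean_od",
    "seed",
    "split",
)


def records_to_manifest(records: list[PatchRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "path": r.path or "",
            "label": r.label,
            "intensity_score": r.truth.intensity_score,
            "proportion_score": r.truth.proportion_score,
            "dab_area_fraction": r.truth.dab_area_fraction,
            "dab_mean_od": r.truth.dab_mean_od,
            "seed": r.seed,
            "split": r.split or "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_dataset(records: list[PatchRecord], out_dir: str) -> str:
    """Write patches as PNG plus a manifest.csv; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    for rec in records:
        rec.path = os.path.join(out_dir, f"{rec.id}.png")
        image = rec.image
        if image.dtype != np.uint8:
            image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)
        Image.fromarray(image).save(rec.path)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    records_to_manifest(records).to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(manifest_path: str) -> list[PatchRecord]:
    """Rebuild records from a manifest.csv written by :func:`write_dataset`."""
    df = pd.read_csv(manifest_path, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        image = np.asarray(Image.open(row["path"]).convert("RGB"))
        truth = PatchTruth(
            int(row["intensity_score"]),
            int(row["proportion_score"]),
            float(row["dab_area_fraction"]),
            float(row["dab_mean_od"]),
        )
        records.append(
            PatchRecord(
                id=row["id"],
                image=image,
                label=row["label"],
                truth=truth,
                seed=int(row["seed"]),
                path=row["path"],
                split=row["split"] or None,
            )
        )
    return records
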