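"""Synthetic colonoscopy-phantom frames, augmentation and dataset assembly.

The generator emulates the *structure* of a colonoscopy polyp dataset —
four visually separable classes, class imbalance fixed by two-stage
augmentation, and a reserved unseen test split — without any claim of
clinical realism.  A frame is a pink mucosa field with a dark lumen,
meandering vessels, sensor noise and, for the three polyp classes, a raised
lesion whose morphology follows the ordinary meaning of the histological
descriptors:

* hyperplastic — small smooth dome (low lobulation, soft boundary)
* adenomatous  — larger lobulated mass with a sharper boundary
* serrated     — flat elevation with a high-frequency saw-tooth margin

Boundary raggedness and edge sharpness are ordered by construction
(serrated > adenomatous > hyperplastic), which keeps the classes separable
and measurable via the rim gradient-energy statistic below.

Everything is reproducible from (spec, seed): identical calls are
byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("normal", "hyperplastic", "adenomatous", "serrated")
BINARY_CLASSES = ("normal", "polyp")
POLYP_SUBTYPES = ("hyperplastic", "adenomatous", "serrated")

MANIFEST_COLUMNS = ("path", "label", "split", "provenance", "origin_id", "seed")

__all__ = [
    "CLASSES",
    "BINARY_CLASSES",
    "AUGMENTATIONS",
    "PhantomSpec",
    "PolypParams",
    "ImageDataset",
    "sample_spec",
    "generate_image",
    "polyp_mask",
    "rim_gradient_energy",
    "generate_dataset",
    "augment",
    "balance_and_expand",
    "make_splits",
    "validate_manifest",
    "nearest_template_accuracy",
]


# ---------------------------------------------------------------------------
# phantom morphology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolypParams:
    """Lesion geometry, all lengths as fractions of the image side."""

    center: tuple[float, float]  # (y, x)
    radius: float
    elevation: float             # brightness amplitude of the dome
    lobulation_count: int
    lobulation_amp: float        # low-frequency boundary modulation
    serration_amp: float         # high-frequency boundary modulation
    serration_freq: int
    edge_softness: float         # boundary transition width (fraction)
    phase: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one synthetic frame."""

    image_size: int
    label: str
    lumen_center: tuple[float, float] = (0.5, 0.5)
    lumen_radius: float = 0.18
    mucosa_color: tuple[float, float, float] = (0.76, 0.45, 0.42)
    vignette_strength: float = 0.35
    vessel_count: int = 6
    polyp: PolypParams | None = None
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.label not in CLASSES and self.label != "polyp":
            raise ValueError(f"unknown label {self.label!r}")
        if (self.polyp is None) != (self.label == "normal"):
            raise ValueError("polyp params must be present iff label != normal")
        if self.polyp is not None:
            cy, cx = self.polyp.center
            r = self.polyp.radius
            if not (r < cy < 1 - r and r < cx < 1 - r):
                raise ValueError("polyp geometry extends outside the image")


def _sample_polyp(label: str, rng: np.random.Generator) -> PolypParams:
    # lesion-centred framing, as in curated clinical ROI datasets: the
    # lesion sits near the image centre with a small positional jitter
    center = tuple(0.5 + rng.uniform(-0.06, 0.06, size=2))
    if label == "hyperplastic":
        return PolypParams(
            center=center,
            radius=rng.uniform(0.08, 0.12),
            elevation=rng.uniform(0.45, 0.60),
            lobulation_count=int(rng.integers(2, 4)),
            lobulation_amp=rng.uniform(0.01, 0.04),
            serration_amp=rng.uniform(0.0, 0.01),
            serration_freq=8,
            edge_softness=rng.uniform(0.055, 0.085),
            phase=rng.uniform(0, 2 * math.pi),
        )
    if label == "adenomatous":
        return PolypParams(
            center=center,
            radius=rng.uniform(0.16, 0.20),
            elevation=rng.uniform(0.60, 0.80),
            lobulation_count=int(rng.integers(3, 6)),
            lobulation_amp=rng.uniform(0.12, 0.20),
            serration_amp=rng.uniform(0.01, 0.03),
            serration_freq=int(rng.integers(8, 11)),
            edge_softness=rng.uniform(0.028, 0.045),
            phase=rng.uniform(0, 2 * math.pi),
        )
    if label == "serrated":
        return PolypParams(
            center=center,
            radius=rng.uniform(0.13, 0.18),
            elevation=rng.uniform(0.22, 0.38),
            lobulation_count=int(rng.integers(2, 4)),
            lobulation_amp=rng.uniform(0.02, 0.05),
            serration_amp=rng.uniform(0.08, 0.12),
            serration_freq=int(rng.integers(12, 19)),
            edge_softness=rng.uniform(0.012, 0.022),
            phase=rng.uniform(0, 2 * math.pi),
        )
    raise ValueError(f"no polyp morphology for label {label!r}")


def sample_spec(label: str, seed: int, image_size: int = 64) -> PhantomSpec:
    """Draw one class-conditional phantom spec from a seeded RNG.

    A binary ``"polyp"`` label samples one of the three subtypes uniformly.
    """
    rng = np.random.default_rng(seed)
    actual = label
    if label == "polyp":
        actual = POLYP_SUBTYPES[int(rng.integers(0, 3))]
    polyp = None if actual == "normal" else _sample_polyp(actual, rng)
    # endoscope-style illumination: bright centre, falloff toward the
    # frame border (the receding lumen darkens the periphery)
    lumen_center = tuple(0.5 + rng.uniform(-0.04, 0.04, size=2))
    return PhantomSpec(
        image_size=image_size,
        label=label,
        lumen_center=lumen_center,
        lumen_radius=rng.uniform(0.13, 0.17),
        mucosa_color=(
            rng.uniform(0.74, 0.80),
            rng.uniform(0.44, 0.48),
            rng.uniform(0.41, 0.45),
        ),
        vignette_strength=rng.uniform(0.35, 0.45),
        vessel_count=int(rng.integers(3, 6)),
        polyp=polyp,
        noise_sd=rng.uniform(0.015, 0.025),
        seed=seed,
    )


def _rim_radius(polyp: PolypParams, phi: np.ndarray) -> np.ndarray:
    """Angle-dependent lesion radius with lobulation + serration."""
    return polyp.radius * (
        1.0
        + polyp.lobulation_amp * np.cos(polyp.lobulation_count * phi + polyp.phase)
        + polyp.serration_amp * np.cos(polyp.serration_freq * phi + 2.1 * polyp.phase)
    )


def _polyp_fields(spec: PhantomSpec):
    """(soft mask, dome profile, signed distance) on the pixel grid."""
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n] / n
    cy, cx = spec.polyp.center
    d = np.hypot(yy - cy, xx - cx)
    phi = np.arctan2(yy - cy, xx - cx)
    rim = _rim_radius(spec.polyp, phi)
    signed = d - rim
    soft = 1.0 / (1.0 + np.exp(signed / max(spec.polyp.edge_softness, 1e-4)))
    dome = np.clip(1.0 - (d / np.maximum(rim, 1e-6)) ** 2, 0.0, 1.0)
    return soft, dome, signed


def generate_image(spec: PhantomSpec) -> np.ndarray:
    """Render one 8-bit RGB phantom frame; byte-identical for equal specs."""
    n = spec.image_size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:n, 0:n] / n
    img = np.empty((n, n, 3))
    for c, base in enumerate(spec.mucosa_color):
        img[..., c] = base
    # mucosal shading: gentle large-scale illumination gradient
    grad_dir = rng.uniform(0, 2 * math.pi)
    img += 0.04 * (np.cos(grad_dir) * (yy - 0.5) + np.sin(grad_dir) * (xx - 0.5))[
        ..., None
    ]
    # illumination vignette: bright plateau at the centre, smooth falloff
    # toward the frame border (the lumen recedes behind the mucosal wall)
    ly, lx = spec.lumen_center
    d_lumen = np.hypot(yy - ly, xx - lx)
    falloff = np.clip(
        (d_lumen - spec.lumen_radius) / (0.72 - spec.lumen_radius), 0.0, 1.0
    )
    darkening = 1.0 - spec.vignette_strength * falloff**2
    img *= darkening[..., None]
    # vessels: meandering darker-red polylines
    for _ in range(spec.vessel_count):
        y, x = rng.uniform(0, n - 1, size=2)
        angle = rng.uniform(0, 2 * math.pi)
        for _ in range(int(2.5 * n)):
            angle += rng.normal(0, 0.3)
            y = np.clip(y + math.sin(angle), 0, n - 1)
            x = np.clip(x + math.cos(angle), 0, n - 1)
            iy, ix = int(y), int(x)
            img[iy, ix, 0] *= 0.88
            img[iy, ix, 1] *= 0.75
            img[iy, ix, 2] *= 0.75
    # polyp lesion
    if spec.polyp is not None:
        soft, dome, signed = _polyp_fields(spec)
        bump = spec.polyp.elevation * soft * (0.35 + 0.65 * dome)
        img[..., 0] += 0.38 * bump
        img[..., 1] += 0.20 * bump
        img[..., 2] += 0.17 * bump
        # specular highlight at the apex of raised lesions
        img += (0.30 * spec.polyp.elevation * dome**3 * soft)[..., None]
        # rim shadow: sharp darkening right at the boundary
        rim_band = np.exp(-((signed / max(spec.polyp.edge_softness, 1e-4)) ** 2))
        img *= (1.0 - 0.35 * rim_band)[..., None]
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def polyp_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean lesion mask (empty for normal frames)."""
    if spec.polyp is None:
        return np.zeros((spec.image_size, spec.image_size), dtype=bool)
    _, _, signed = _polyp_fields(spec)
    return signed <= 0


def rim_gradient_energy(image: np.ndarray, spec: PhantomSpec,
                        band: float = 0.03) -> float:
    """Mean squared gray-level gradient within a band around the lesion rim.

    The boundary-roughness statistic: saw-tooth margins and sharp edges
    produce high gradient energy, smooth soft domes low energy.
    """
    if spec.polyp is None:
        raise ValueError("normal frames have no rim")
    gray = np.asarray(image, dtype=float).mean(axis=-1) / 255.0
    gy, gx = np.gradient(gray)
    energy = gy**2 + gx**2
    _, _, signed = _polyp_fields(spec)
    ring = np.abs(signed) < band
    return float(energy[ring].mean())


# ---------------------------------------------------------------------------
# augmentation registry (exactly 21 named, seeded, shape-preserving ops)
# ---------------------------------------------------------------------------


def _warp(img: np.ndarray, transform) -> np.ndarray:
    from skimage.transform import warp

    return warp(img, transform.inverse, mode="reflect", preserve_range=True)


def _aug_h_flip(img, rng):
    return img[:, ::-1]


def _aug_v_flip(img, rng):
    return img[::-1]


def _aug_rot90(img, rng):
    return np.rot90(img, 1)


def _aug_rot180(img, rng):
    return np.rot90(img, 2)


def _aug_rot270(img, rng):
    return np.rot90(img, 3)


def _aug_rotate_small(img, rng, max_angle: float = 15.0):
    from skimage.transform import rotate

    angle = rng.uniform(-max_angle, max_angle)
    return rotate(img, angle, mode="reflect", preserve_range=True)


def _aug_translate(img, rng, max_shift: float = 0.10):
    from skimage.transform import AffineTransform

    n = img.shape[0]
    ty, tx = rng.uniform(-max_shift * n, max_shift * n, size=2)
    return _warp(img, AffineTransform(translation=(tx, ty)))


def _aug_zoom_in(img, rng, factor: float = 1.2):
    from skimage.transform import AffineTransform

    n = img.shape[0]
    shift = n * (1 - factor) / 2
    return _warp(img, AffineTransform(scale=factor, translation=(shift, shift)))


def _aug_zoom_out(img, rng, factor: float = 0.8):
    from skimage.transform import AffineTransform

    n = img.shape[0]
    shift = n * (1 - factor) / 2
    return _warp(img, AffineTransform(scale=factor, translation=(shift, shift)))


def _aug_shear(img, rng, max_shear: float = 0.2):
    from skimage.transform import AffineTransform

    return _warp(img, AffineTransform(shear=rng.uniform(-max_shear, max_shear)))


def _aug_brightness_up(img, rng, delta: float = 0.12):
    return img + delta


def _aug_brightness_down(img, rng, delta: float = 0.12):
    return img - delta


def _aug_contrast_up(img, rng, factor: float = 1.3):
    return (img - 0.5) * factor + 0.5


def _aug_contrast_down(img, rng, factor: float = 0.7):
    return (img - 0.5) * factor + 0.5


def _aug_gamma(img, rng):
    return np.clip(img, 0, 1) ** rng.uniform(0.7, 1.4)


def _aug_saturation_shift(img, rng):
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(np.clip(img, 0, 1))
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.7, 1.3), 0, 1)
    return hsv2rgb(hsv)


def _aug_gaussian_noise(img, rng, sd: float = 0.03):
    return img + rng.normal(0, sd, size=img.shape)


def _aug_salt_pepper(img, rng, amount: float = 0.01):
    out = img.copy()
    mask = rng.random(img.shape[:2])
    out[mask < amount / 2] = 0.0
    out[mask > 1 - amount / 2] = 1.0
    return out


def _aug_gaussian_blur(img, rng, sigma: float = 1.0):
    from skimage.filters import gaussian

    return gaussian(img, sigma=sigma, channel_axis=-1)


def _aug_sharpen(img, rng, radius: float = 1.5, amount: float = 1.0):
    # explicit unsharp mask: img + amount * (img - blur(img))
    from skimage.filters import gaussian

    img = np.clip(img, 0, 1)
    blurred = gaussian(img, sigma=radius, channel_axis=-1)
    return img + amount * (img - blurred)


def _aug_cutout(img, rng, fraction: float = 0.2):
    out = img.copy()
    n = img.shape[0]
    k = max(1, int(fraction * n))
    y = int(rng.integers(0, n - k + 1))
    x = int(rng.integers(0, img.shape[1] - k + 1))
    out[y : y + k, x : x + k] = img.mean(axis=(0, 1))
    return out


#: the fixed, versioned registry of augmentation techniques
AUGMENTATIONS: dict[str, Callable] = {
    "h_flip": _aug_h_flip,
    "v_flip": _aug_v_flip,
    "rot90": _aug_rot90,
    "rot180": _aug_rot180,
    "rot270": _aug_rot270,
    "rotate_small": _aug_rotate_small,
    "translate": _aug_translate,
    "zoom_in": _aug_zoom_in,
    "zoom_out": _aug_zoom_out,
    "shear": _aug_shear,
    "brightness_up": _aug_brightness_up,
    "brightness_down": _aug_brightness_down,
    "contrast_up": _aug_contrast_up,
    "contrast_down": _aug_contrast_down,
    "gamma": _aug_gamma,
    "saturation_shift": _aug_saturation_shift,
    "gaussian_noise": _aug_gaussian_noise,
    "salt_pepper": _aug_salt_pepper,
    "gaussian_blur": _aug_gaussian_blur,
    "sharpen": _aug_sharpen,
    "cutout": _aug_cutout,
}
assert len(AUGMENTATIONS) == 21


def augment(image: np.ndarray, op: str, seed: int = 0, **params) -> np.ndarray:
    """Apply one registered augmentation to an 8-bit RGB image.

    Output has identical shape and dtype; the op's stochastic parameters
    are drawn from a RNG seeded by ``seed``.
    """
    if op not in AUGMENTATIONS:
        raise ValueError(
            f"unknown augmentation {op!r}; registry: {sorted(AUGMENTATIONS)}"
        )
    img = np.asarray(image)
    if img.dtype != np.uint8 or img.ndim != 3:
        raise ValueError("image must be 8-bit RGB (H, W, 3)")
    rng = np.random.default_rng(seed)
    out = AUGMENTATIONS[op](img.astype(float) / 255.0, rng, **params)
    return (np.clip(out, 0.0, 1.0) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class ImageDataset:
    """In-memory image store plus its manifest.

    Manifest columns: path, label, split (train/val/test), provenance
    (original/augmented), origin_id (the original frame an augmented image
    derives from; originals point to themselves), seed.
    """

    images: dict[str, np.ndarray] = field(default_factory=dict)
    manifest: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    )

    def subset(self, split: str) -> "ImageDataset":
        sub = self.manifest[self.manifest["split"] == split].reset_index(drop=True)
        return ImageDataset({p: self.images[p] for p in sub["path"]}, sub)

    def arrays(self, split: str | None = None,
               classes: Sequence[str] | None = None):
        """(X, y): stacked images in [0, 1] float and integer labels."""
        mf = self.manifest
        if split is not None:
            mf = mf[mf["split"] == split]
        if classes is None:
            present = set(mf["label"])
            canonical = [c for c in CLASSES + ("polyp",) if c in present]
            classes = tuple(canonical) if set(canonical) == present else tuple(
                sorted(present)
            )
        else:
            classes = tuple(classes)
        X = np.stack([self.images[p] for p in mf["path"]]).astype(float) / 255.0
        y = np.array([classes.index(l) for l in mf["label"]])
        return X, y

    def save(self, out_dir: str | Path) -> Path:
        from PIL import Image

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for path, img in self.images.items():
            Image.fromarray(img).save(out_dir / path)
        self.manifest.to_csv(out_dir / "manifest.csv", index=False)
        return out_dir / "manifest.csv"

    @classmethod
    def load(cls, manifest_path: str | Path) -> "ImageDataset":
        from PIL import Image

        manifest_path = Path(manifest_path)
        manifest = pd.read_csv(manifest_path, keep_default_na=False)
        images = {
            p: np.asarray(Image.open(manifest_path.parent / p).convert("RGB"))
            for p in manifest["path"]
        }
        return cls(images, manifest)


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(manifest["split"]) - {"train", "val", "test"}
    if bad:
        raise ValueError(f"invalid split values: {sorted(bad)}")
    test = manifest[manifest["split"] == "test"]
    if (test["provenance"] == "augmented").any():
        raise ValueError("augmented images must never enter the test split")
    # leakage guard: no train/val image derives from a test original
    test_origins = set(test["origin_id"])
    trainval = manifest[manifest["split"].isin(("train", "val"))]
    leaked = set(trainval["origin_id"]) & test_origins
    if leaked:
        raise ValueError(f"derivatives of test originals in train/val: {sorted(leaked)[:5]}")


def generate_dataset(
    counts: Mapping[str, int], image_size: int = 64, seed: int = 0
) -> ImageDataset:
    """Generate ``counts[label]`` original phantoms per class."""
    ss = np.random.SeedSequence(seed)
    images: dict[str, np.ndarray] = {}
    rows = []
    child_seeds = iter(int(s) % (2**31) for s in ss.generate_state(sum(counts.values())))
    for label, count in counts.items():
        for i in range(count):
            s = next(child_seeds)
            spec = sample_spec(label, s, image_size)
            path = f"{label}_{i:04d}.png"
            images[path] = generate_image(spec)
            rows.append((path, label, "train", "original", path, s))
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return ImageDataset(images, manifest)


def _expand_class(ds: ImageDataset, rows: pd.DataFrame, target: int,
                  rng: np.random.Generator, new_rows: list) -> None:
    ops = sorted(AUGMENTATIONS)
    current = len(rows)
    originals = rows[rows["provenance"] == "original"]
    pool = originals if len(originals) else rows
    k = 0
    while current < target:
        src = pool.iloc[k % len(pool)]
        op = ops[k % len(ops)]
        seed = int(rng.integers(0, 2**31))
        img = augment(ds.images[src["path"]], op, seed)
        path = f"{Path(src['path']).stem}__aug{k:04d}_{op}.png"
        ds.images[path] = img
        new_rows.append(
            (path, src["label"], src["split"], "augmented", src["origin_id"], seed)
        )
        current += 1
        k += 1


def balance_and_expand(
    ds: ImageDataset,
    stage1_target: int | None = None,
    stage2_target: int | None = None,
    seed: int = 0,
) -> ImageDataset:
    """Two-stage augmentation over the non-test pool.

    Stage 1 equalizes per-class counts (default target: the current maximum
    class count) by augmenting originals; stage 2 further multiplies every
    class to ``stage2_target``.  Test rows are never augmented and augmented
    images never enter the test split.
    """
    manifest = ds.manifest.copy()
    pool = manifest[manifest["split"] != "test"]
    counts = pool["label"].value_counts()
    t1 = int(counts.max()) if stage1_target is None else int(stage1_target)
    if t1 < counts.max():
        raise ValueError(
            f"stage-1 target {t1} below current maximum class count {counts.max()}"
        )
    targets = [t1] if stage2_target is None else [t1, int(stage2_target)]
    if stage2_target is not None and int(stage2_target) < t1:
        raise ValueError("stage-2 target below stage-1 target")
    out = ImageDataset(dict(ds.images), manifest)
    rng = np.random.default_rng(seed)
    for target in targets:
        new_rows: list = []
        pool = out.manifest[out.manifest["split"] != "test"]
        for label, rows in pool.groupby("label"):
            if len(rows) > target:
                raise ValueError(
                    f"target {target} below current count {len(rows)} for {label!r}"
                )
            _expand_class(out, rows, target, rng, new_rows)
        if new_rows:
            out.manifest = pd.concat(
                [out.manifest, pd.DataFrame(new_rows, columns=list(MANIFEST_COLUMNS))],
                ignore_index=True,
            )
    return out


def make_splits(
    ds: ImageDataset,
    holdout_counts: Mapping[str, int],
    ratio: float = 0.8,
    seed: int = 0,
) -> ImageDataset:
    """Reserve the unseen test originals, then stratified train/val split.

    Test images are drawn from originals only; any augmented derivative of a
    test original is removed from the pool (strict leakage guard).  The
    remainder is split per class with ``round(ratio * n)`` training images.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie strictly between 0 and 1 "
                         "(validation must be non-empty)")
    rng = np.random.default_rng(seed)
    manifest = ds.manifest.copy().reset_index(drop=True)
    manifest["split"] = "train"
    has_derivative = set(
        manifest.loc[manifest["provenance"] == "augmented", "origin_id"]
    )
    test_paths: set[str] = set()
    for label, count in holdout_counts.items():
        cand = manifest[
            (manifest["label"] == label) & (manifest["provenance"] == "original")
        ]
        if count > len(cand):
            raise ValueError(
                f"cannot hold out {count} originals of {label!r}; only {len(cand)}"
            )
        # prefer originals without augmented derivatives, so holding them
        # out costs no training images under the leakage guard
        idx = cand.index.to_numpy()
        clean = idx[~cand["path"].isin(has_derivative).to_numpy()]
        dirty = idx[cand["path"].isin(has_derivative).to_numpy()]
        ordered = np.concatenate([rng.permutation(clean), rng.permutation(dirty)])
        picked = ordered[:count]
        manifest.loc[picked, "split"] = "test"
        test_paths.update(manifest.loc[picked, "path"])
    # leakage guard: drop derivatives of test originals
    is_test = manifest["split"] == "test"
    leaked = (~is_test) & manifest["origin_id"].isin(test_paths) & (
        manifest["provenance"] == "augmented"
    )
    manifest = manifest[~leaked].reset_index(drop=True)
    for label, rows in manifest[manifest["split"] != "test"].groupby("label"):
        idx = rng.permutation(rows.index.to_numpy())
        n_train = int(round(ratio * len(idx)))
        if n_train == len(idx):
            n_train -= 1  # keep validation non-empty per class
        manifest.loc[idx[n_train:], "split"] = "val"
    images = {p: ds.images[p] for p in manifest["path"]}
    out = ImageDataset(images, manifest)
    validate_manifest(out.manifest)
    return out


def nearest_template_accuracy(X: np.ndarray, y: np.ndarray, seed: int = 0,
                              train_fraction: float = 0.5) -> float:
    """Accuracy of class-mean template matching (separability certificate)."""
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.permutation(n)
    n_train = int(train_fraction * n)
    tr, te = idx[:n_train], idx[n_train:]
    classes = np.unique(y)
    templates = np.stack([X[tr][y[tr] == c].mean(axis=0) for c in classes])
    flat = X[te].reshape(len(te), -1)
    dists = ((flat[:, None, :] - templates.reshape(len(classes), -1)[None]) ** 2).sum(-1)
    pred = classes[dists.argmin(axis=1)]
    return float((pred == y[te]).mean())
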