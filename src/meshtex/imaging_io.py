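"""Image I/O, synthetic texture fixtures, and training-set augmentation.

Everything downstream of this module consumes 8-bit grayscale arrays
(``uint8``, shape ``(H, W)``).  Color photographs are reduced to luminance
on load; three seeded texture generators stand in for lesion photographs so
the whole pipeline is exercisable without any dataset download.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import rotate

__all__ = [
    "LabeledSet",
    "AugmentPolicy",
    "load_image",
    "save_image",
    "generate_texture_fixture",
    "make_labeled_set",
    "augment",
    "load_labeled_directory",
    "write_manifest",
]

#: BT.601 luminance weights applied to RGB inputs.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Smallest image the descriptor stage can consume (largest window is 7x7).
MIN_SIZE = 7

TEXTURE_CLASSES = ("smooth", "speckle", "grating")


@dataclass
class LabeledSet:
    """An ordered collection of grayscale images with parallel class labels.

    ``origins`` tracks, for every image, the index of the original image it
    derives from (itself for originals); augmentation fills it in so that
    cross-validation can keep an original and its variants on the same side
    of every fold boundary.
    """

    images: list[np.ndarray]
    labels: list[str]
    class_names: list[str]
    origins: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        missing = set(self.labels) - set(self.class_names)
        if missing:
            raise ValueError(f"labels not listed in class_names: {sorted(missing)}")
        if not self.origins:
            self.origins = list(range(len(self.images)))
        elif len(self.origins) != len(self.images):
            raise ValueError("origins must parallel images")

    def __len__(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class AugmentPolicy:
    """Deterministic geometric augmentation: how many variants per original.

    The two stock transforms — horizontal flip and a +15 deg rotation with
    reflect padding — are label-preserving for texture classes.  With
    ``variants_per_original`` > 2 the transform list cycles (flip of the
    rotated image, and so on).
    """

    variants_per_original: int = 2
    rotation_deg: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variants_per_original < 0:
            raise ValueError("variants_per_original must be >= 0")


def _as_gray_u8(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = np.rint(arr[..., :3].astype(float) @ _LUMA)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG image as an 8-bit grayscale array.

    Color inputs are converted with BT.601 luminance weights
    (0.299 R + 0.587 G + 0.114 B), rounded to the nearest integer.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB") if im.mode not in ("L", "I;16") else im)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    img = _as_gray_u8(arr)
    if img.shape[0] < MIN_SIZE or img.shape[1] < MIN_SIZE:
        raise ValueError(
            f"image {path} is {img.shape[0]}x{img.shape[1]}; "
            f"the descriptor needs at least {MIN_SIZE}x{MIN_SIZE}"
        )
    return img


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as PNG (lossless; intermediates never use JPEG)."""
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(Path(path))


def generate_texture_fixture(
    class_id: str, size: tuple[int, int] = (32, 32), seed: int = 0
) -> np.ndarray:
    """Generate one seeded synthetic texture image of a given class.

    The three classes differ in second-order statistics:

    - ``smooth``:  heavily low-pass-filtered Gaussian noise (low local SD),
    - ``speckle``: impulsive salt-and-pepper-like high-frequency noise,
    - ``grating``: an oriented sinusoid plus mild Gaussian noise.
    """
    h, w = size
    if h < 16 or w < 16:
        raise ValueError(f"fixture size must be at least 16x16, got {h}x{w}")
    if class_id not in TEXTURE_CLASSES:
        raise ValueError(f"unknown texture class {class_id!r}; use one of {TEXTURE_CLASSES}")
    rng = np.random.default_rng(np.random.SeedSequence([hash_class(class_id), h, w, seed]))

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    if class_id == "smooth":
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(rng.normal(size=(h, w)), sigma=4.0, mode="reflect")
        base = (base - base.min()) / max(np.ptp(base), 1e-12)
        img = 60 + 120 * base
    elif class_id == "speckle":
        img = np.full((h, w), 128.0)
        n_imp = int(0.25 * h * w)
        ys = rng.integers(0, h, n_imp)
        xs = rng.integers(0, w, n_imp)
        img[ys, xs] = rng.choice([20.0, 235.0], size=n_imp)
        img += rng.normal(scale=8.0, size=(h, w))
    else:  # grating
        theta = rng.uniform(np.pi / 6, np.pi / 3)
        freq = rng.uniform(0.25, 0.45)
        phase = rng.uniform(0, 2 * np.pi)
        img = 128 + 90 * np.sin(freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
        img += rng.normal(scale=6.0, size=(h, w))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def hash_class(class_id: str) -> int:
    """Stable small integer per class name (Python's hash() is salted per run)."""
    return sum(ord(c) * 31**k for k, c in enumerate(class_id)) % (2**31)


def make_labeled_set(
    n_per_class: int,
    classes: Sequence[str] = TEXTURE_CLASSES,
    size: tuple[int, int] = (32, 32),
    seed: int = 0,
) -> LabeledSet:
    """Build a balanced seeded fixture dataset: ``n_per_class`` images per class.

    Class names that are not texture-generator names are mapped cyclically
    onto the three generators, so arbitrary label sets still get distinct
    textures per class (up to three distinct classes).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    classes = list(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    images, labels = [], []
    for ci, cls in enumerate(classes):
        texture = cls if cls in TEXTURE_CLASSES else TEXTURE_CLASSES[ci % 3]
        for k in range(n_per_class):
            images.append(generate_texture_fixture(texture, size,
                                                   seed=seed * 100_003 + k))
            labels.append(cls)
    return LabeledSet(images=images, labels=labels, class_names=classes)


def _variant(img: np.ndarray, k: int, policy: AugmentPolicy) -> np.ndarray:
    """k-th deterministic variant: flip, rotate, then flip-of-rotate, ..."""
    out = np.asarray(img, dtype=float)
    if k % 2 == 0:
        out = out[:, ::-1]
    if k >= 1:
        deg = policy.rotation_deg * (1 + k // 2)
        out = rotate(out, deg, mode="reflect", preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment(dataset: LabeledSet, policy: AugmentPolicy) -> LabeledSet:
    """Append ``variants_per_original`` transformed copies of every image.

    Originals come first in their input order; variants follow in
    deterministic (original-index, variant-index) order.  Each variant
    records the index of its source image in ``origins`` so evaluation code
    can keep variants from leaking across fold or train/test boundaries.
    """
    images = list(dataset.images)
    labels = list(dataset.labels)
    origins = list(dataset.origins)
    for idx, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
        for k in range(policy.variants_per_original):
            images.append(_variant(img, k, policy))
            labels.append(lab)
            origins.append(dataset.origins[idx])
    return LabeledSet(images=images, labels=labels,
                      class_names=list(dataset.class_names), origins=origins)


def load_labeled_directory(root: str | Path) -> LabeledSet:
    """Read a directory-per-class layout: ``root/<label>/*.png|jpg|jpeg``."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no such dataset directory: {root}")
    images, labels, class_names = [], [], []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        class_names.append(cls_dir.name)
        for f in sorted(cls_dir.iterdir()):
            if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                images.append(load_image(f))
                labels.append(cls_dir.name)
    if not images:
        raise FileNotFoundError(f"no images found under {root}")
    return LabeledSet(images=images, labels=labels, class_names=class_names)


def write_manifest(dataset: LabeledSet, paths: Sequence[str], out: str | Path) -> None:
    """Write a two-column (path, label) delimited manifest for a labeled set."""
    with open(out, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["path", "label"])
        for p, lab in zip(paths, dataset.labels):
            wr.writerow([p, lab])
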