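"""Synthetic study data: texture image tasks, patient slice stacks,
slides with blank margins, and sparse-signal regression tables.

The real study conditions (ImageNet-scale natural images, TCGA lung WSI
tiles, two-center CT cohorts) are emulated by a controllable family of
class-conditional textures: a fixed-phase oriented grating per class, a
grid of Gaussian blobs (count per class), and band-limited noise.  The
fixed phase puts class means apart in pixel space, so the tasks are
separable by construction - a linear probe on raw pixels reaches > 0.9
training accuracy at the default sizes - while the noise keeps them
non-trivial for a CNN.

Everything is generated from an explicit seed; identical specs produce
bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import TILE, stack_slices


@dataclass(frozen=True)
class TextureParams:
    """One class's texture: grating frequency (cycles/pixel), orientation
    (radians), grating amplitude, and blob count."""

    frequency: float
    orientation: float
    amplitude: float = 0.18
    n_blobs: int = 0


def default_texture_params(n_classes: int):
    return tuple(
        TextureParams(frequency=0.06 + 0.05 * c,
                      orientation=np.pi * c / max(n_classes, 2),
                      n_blobs=c)
        for c in range(n_classes)
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one labeled texture task; identical specs give
    bit-identical batches."""

    n_per_class: int
    n_classes: int = 2
    image_size: int = 64
    texture_params: tuple = ()
    noise_sd: float = 0.1
    seed: int = 0
    task_id: str = "source1"

    def validate(self):
        if self.n_per_class < 1 or self.n_classes < 1 or self.image_size < 1:
            raise ValueError("sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class LabeledImageBatch:
    """images: (N, 3, H, W) floats in [0, 1]; labels: int class per image."""

    images: np.ndarray
    labels: np.ndarray
    task_id: str

    def __post_init__(self):
        if self.images.ndim != 4 or self.images.shape[0] < 1:
            raise ValueError("images must be a non-empty 4-D array")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError("one label per image required")


@dataclass
class PatientRecord:
    """One patient: stacked 3-channel 224x224 lesion slices, a binary
    label (0 = granuloma-like, 1 = adenocarcinoma-like), and the deep
    feature vector filled in by feature extraction."""

    patient_id: str
    slices: list
    label: int
    features: np.ndarray | None = None


def _grating(size: int, p: TextureParams) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    phase = 2 * np.pi * p.frequency * (xx * np.cos(p.orientation)
                                       + yy * np.sin(p.orientation))
    return p.amplitude * np.cos(phase)


def _blob_field(size: int, p: TextureParams, rng, jitter_sd: float) -> np.ndarray:
    if p.n_blobs == 0:
        return np.zeros((size, size), dtype=np.float32)
    out = np.zeros((size, size), dtype=np.float32)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    sigma = size / 12.0
    # blobs on a fixed diagonal grid; jitter only when noise is on
    for b in range(p.n_blobs):
        cy = size * (b + 1.0) / (p.n_blobs + 1.0)
        cx = size * (b + 1.0) / (p.n_blobs + 1.0)
        if jitter_sd > 0:
            cy += rng.normal(0.0, jitter_sd * size)
            cx += rng.normal(0.0, jitter_sd * size)
        out += 0.15 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return out


def _bandpass_noise(size: int, p: TextureParams, rng, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros((size, size), dtype=np.float32)
    white = rng.normal(0.0, 1.0, (size, size))
    f = np.fft.fftfreq(size)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    r = np.sqrt(fx ** 2 + fy ** 2)
    band = np.exp(-((r - p.frequency) ** 2) / (2 * (0.03) ** 2))
    shaped = np.fft.ifft2(np.fft.fft2(white) * band).real
    s = shaped.std()
    if s > 0:
        shaped = shaped / s
    return (sd * shaped).astype(np.float32)


def _class_image(size: int, p: TextureParams, rng, noise_sd: float) -> np.ndarray:
    jitter = 0.02 if noise_sd > 0 else 0.0
    img = 0.5 + _grating(size, p) + _blob_field(size, p, rng, jitter) \
        + _bandpass_noise(size, p, rng, noise_sd)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return np.stack([img, img, img], axis=0)


def gen_task(spec: SyntheticSpec) -> LabeledImageBatch:
    """Generate a labeled texture-classification task per ``spec``."""
    spec.validate()
    params = spec.texture_params or default_texture_params(spec.n_classes)
    if len(params) != spec.n_classes:
        raise ValueError("one TextureParams per class required")
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for c in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            images.append(_class_image(spec.image_size, params[c], rng, spec.noise_sd))
            labels.append(c)
    return LabeledImageBatch(np.stack(images), np.array(labels, dtype=np.int64),
                             spec.task_id)


def gen_patient_cohort(n_patients: int, slices_range=(3, 6), class_balance=0.5,
                       seed: int = 0, image_size: int = TILE,
                       noise_sd: float = 0.1) -> list:
    """Emulate a CT cohort: each patient gets a class label (Bernoulli with
    ``class_balance`` probability of class 1), a slice count drawn
    uniformly from ``slices_range`` (inclusive), and a class-dependent
    texture injected into every slice.  Raw 2-D slices are stacked into
    3-channel images with the sliding-triple rule."""
    if slices_range[0] < 3 or slices_range[1] < slices_range[0]:
        raise ValueError("slices_range must satisfy 3 <= lo <= hi")
    if n_patients < 1:
        raise ValueError("need at least one patient")
    params = default_texture_params(2)
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        label = int(rng.random() < class_balance)
        n_stacked = int(rng.integers(slices_range[0], slices_range[1] + 1))
        raw = [_class_image(image_size, params[label], rng, noise_sd)[0]
               for _ in range(n_stacked + 2)]
        cohort.append(PatientRecord(patient_id=f"P{i:04d}",
                                    slices=stack_slices(raw), label=label))
    return cohort


def gen_synthetic_wsi(x: int, y: int, blank_fraction: float, seed: int = 0) -> np.ndarray:
    """A (y, x, 3) slide whose 224-grid contains ``round(blank_fraction*K)``
    near-white tiles (mean intensity > 0.95), the rest textured tissue."""
    if not (0.0 <= blank_fraction <= 1.0):
        raise ValueError("blank_fraction must lie in [0, 1]")
    if x < TILE or y < TILE:
        raise ValueError(f"slide must be at least {TILE} pixels on each side")
    rng = np.random.default_rng(seed)
    ny, nx = -(-y // TILE), -(-x // TILE)
    k = ny * nx
    n_blank = int(round(blank_fraction * k))
    blank_idx = set(rng.choice(k, size=n_blank, replace=False).tolist())
    slide = np.empty((y, x, 3), dtype=np.float32)
    params = default_texture_params(2)[1]
    idx = 0
    for r in range(ny):
        for c in range(nx):
            r0, c0 = r * TILE, c * TILE
            h = min(TILE, y - r0)
            w = min(TILE, x - c0)
            if idx in blank_idx:
                patch = rng.uniform(0.97, 1.0, (h, w, 1)).astype(np.float32)
                slide[r0:r0 + h, c0:c0 + w] = patch
            else:
                tex = _class_image(TILE, params, rng, 0.1)[0]
                slide[r0:r0 + h, c0:c0 + w] = tex[:h, :w, None] * 0.8
            idx += 1
    return slide


def gen_sparse_regression(n: int, d: int, k_relevant: int, noise_sd: float,
                          seed: int = 0):
    """Design matrix X ~ N(0,1), targets X @ w + noise with exactly
    ``k_relevant`` nonzero entries of w.  Returns (X, t, w_true)."""
    if n < 2:
        raise ValueError("need at least two samples")
    if not (0 <= k_relevant <= d):
        raise ValueError("k_relevant must lie in [0, D]")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, (n, d))
    w = np.zeros(d)
    if k_relevant > 0:
        support = rng.choice(d, size=k_relevant, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k_relevant)
        w[support] = signs * rng.uniform(1.0, 2.0, k_relevant)
    t = x @ w + rng.normal(0.0, noise_sd, n)
    return x, t, w


# -------------------------------------------------------------- disk I/O

def write_cohort(cohort, out_dir) -> Path:
    """Write a cohort as PNG slices plus a CSV manifest
    (patient_id, label, slice paths); returns the manifest path."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["patient_id,label,slice_path"]
    for rec in cohort:
        for j, sl in enumerate(rec.slices):
            arr = (np.clip(np.moveaxis(sl, 0, -1), 0, 1) * 255).astype(np.uint8)
            path = out_dir / f"{rec.patient_id}_s{j:02d}.png"
            Image.fromarray(arr).save(path)
            rows.append(f"{rec.patient_id},{rec.label},{path.name}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
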