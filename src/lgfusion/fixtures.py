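"""Deterministic procedural image fixtures.

The generator emits small class-separable texture images so that the
whole pipeline — feature extraction, fusion, embedding, training,
retrieval — can be exercised end to end without downloading a dataset.
Each class is a distinct procedural texture family (oriented stripes,
checkerboards, Gaussian blob fields, rings, noise fields, gradients)
rendered in a class-specific base colour with within-class jitter in
frequency, phase and amplitude.  The images emulate only the statistical
role of training data (separable texture/colour classes grouped into
scans), not histology appearance.

Everything is reproducible: the same seed yields bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .retrieval import RetrievalRun, ScanPartition

__all__ = [
    "FixtureSpec",
    "generate_texture_dataset",
    "write_texture_dataset",
    "make_toy_retrieval_case",
    "CLASS_PALETTE",
]

# base colours per class prototype, spread far apart in RGB so that class
# mean colours differ by much more than the jitter scale (~0.03)
CLASS_PALETTE = np.array(
    [
        [0.85, 0.30, 0.35],
        [0.30, 0.75, 0.40],
        [0.30, 0.45, 0.85],
        [0.85, 0.75, 0.25],
        [0.70, 0.30, 0.80],
        [0.25, 0.75, 0.75],
        [0.85, 0.55, 0.30],
        [0.55, 0.55, 0.55],
    ]
)
JITTER_SCALE = 0.03


@dataclass(frozen=True)
class FixtureSpec:
    """Size and seed of a procedural fixture dataset."""

    n_classes: int = 8
    n_per_class: int = 16
    image_side: int = 64
    seed: int = 0
    scans_per_class: int = 1

    def __post_init__(self):
        if self.image_side % 32:
            raise ValueError(f"image_side {self.image_side} not divisible by 32")
        if self.n_classes < 1 or self.n_per_class < 1 or self.scans_per_class < 1:
            raise ValueError("counts must be positive")
        if self.scans_per_class > self.n_per_class:
            raise ValueError("more scans than images per class")


def _texture_field(kind: int, side: int, rng: np.random.Generator) -> np.ndarray:
    """One [0, 1] intensity field of the given texture family with jitter."""
    y, x = np.mgrid[0:side, 0:side] / side
    freq = (3.0 + kind % 3) * rng.uniform(0.9, 1.1)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if kind == 0:    # horizontal stripes
        t = np.sin(2 * np.pi * freq * y + phase)
    elif kind == 1:  # vertical stripes
        t = np.sin(2 * np.pi * freq * x + phase)
    elif kind == 2:  # diagonal stripes
        t = np.sin(2 * np.pi * freq * (x + y) + phase)
    elif kind == 3:  # checkerboard
        t = np.sin(2 * np.pi * freq * x + phase) * np.sin(2 * np.pi * freq * y + phase)
    elif kind == 4:  # Gaussian blob field
        t = np.zeros((side, side))
        for _ in range(6):
            cx, cy = rng.uniform(0.1, 0.9, size=2)
            sigma = rng.uniform(0.05, 0.12)
            t += np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
        t = 2.0 * t / max(t.max(), 1e-9) - 1.0
    elif kind == 5:  # band-limited noise field
        coarse = rng.standard_normal((side // 8, side // 8))
        t = np.kron(coarse, np.ones((8, 8)))
        t = np.clip(t / 2.5, -1.0, 1.0)
    elif kind == 6:  # concentric rings
        r = np.hypot(x - 0.5, y - 0.5)
        t = np.sin(2 * np.pi * (freq + 2.0) * r + phase)
    else:            # smooth diagonal gradient
        t = 2.0 * ((x * np.cos(phase / 4) + y * np.sin(phase / 4)) % 1.0) - 1.0
    return 0.5 * (t + 1.0)


def generate_texture_dataset(spec: FixtureSpec):
    """Generate the fixture images and manifest in memory.

    Returns
    -------
    images : ndarray, shape (N, side, side, 3), float64 in [0, 1]
    manifest : pandas.DataFrame with columns id, class, scan
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    images, rows = [], []
    for cls in range(spec.n_classes):
        base = CLASS_PALETTE[cls % len(CLASS_PALETTE)]
        kind = cls % 8
        for i in range(spec.n_per_class):
            t = _texture_field(kind, spec.image_side, rng)
            amp = rng.uniform(0.40, 0.50)
            img = base[None, None, :] * (1.0 - amp + amp * t[:, :, None])
            img = img + rng.standard_normal(img.shape) * JITTER_SCALE
            images.append(np.clip(img, 0.0, 1.0))
            scan = cls * spec.scans_per_class + (i % spec.scans_per_class)
            rows.append(
                {"id": f"c{cls}_i{i}", "class": cls, "scan": scan}
            )
    manifest = pd.DataFrame(rows)
    return np.stack(images), manifest


def write_texture_dataset(spec: FixtureSpec, out_dir: str | Path):
    """Rasterize the fixture dataset to PNG files plus a manifest CSV.

    The manifest's ``path`` column is relative to ``out_dir``.  Returns
    the manifest DataFrame.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, manifest = generate_texture_dataset(spec)
    paths = []
    for img, row in zip(images, manifest.itertuples()):
        name = f"{row.id}.png"
        arr = np.round(img * 255.0).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / name)
        paths.append(name)
    manifest = manifest.assign(path=paths)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def make_toy_retrieval_case() -> tuple[RetrievalRun, ScanPartition]:
    """Worked 2-scan, 5-patch retrieval case with known metric values.

    Scan ``s0`` holds 2 patches of which 1 retrieves within its scan;
    scan ``s1`` holds 3 patches, all retrieving within their scan.  By
    direct enumeration eta_p = 4/5 = 0.8, eta_w = (1/2)(1/2 + 3/3) = 0.75
    and eta_tot = 0.6.
    """
    part = ScanPartition(gamma={"s0": ("p0", "p1"), "s1": ("p2", "p3", "p4")})
    run = RetrievalRun(
        retrieved={
            "p0": ("p1",),  # hit   (s0)
            "p1": ("p2",),  # miss  (s0 -> s1)
            "p2": ("p3",),  # hit   (s1)
            "p3": ("p4",),  # hit   (s1)
            "p4": ("p2",),  # hit   (s1)
        },
        k=1,
    )
    return run, part
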