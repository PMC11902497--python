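"""Dataset access: in-memory arrays and image-folder manifests.

A dataset, for the training loop and the embedder, is anything exposing
``n_images``, ``n_classes``, ``ids``, ``labels``, ``scans`` and
``load(indices) -> (N, side, side, 3) float array in [0, 1]``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["ArrayDataset", "ImageFolderDataset", "load_manifest"]


def load_manifest(path: str | Path):
    """Read a manifest CSV with columns path, class, scan (id optional)."""
    import pandas as pd

    manifest = pd.read_csv(path)
    required = {"path", "class", "scan"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if "id" not in manifest.columns:
        manifest = manifest.assign(id=[Path(p).stem for p in manifest["path"]])
    return manifest


class ArrayDataset:
    """Images already in memory, labelled by a manifest DataFrame."""

    def __init__(self, images: np.ndarray, manifest):
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or len(images) != len(manifest):
            raise ValueError("images and manifest row counts disagree")
        if len(manifest) == 0:
            raise ValueError("empty dataset")
        self.images = images
        self.manifest = manifest.reset_index(drop=True)
        self.ids = list(self.manifest["id"])
        self.labels = np.asarray(self.manifest["class"], dtype=np.int64)
        self.scans = list(self.manifest["scan"])

    @property
    def n_images(self) -> int:
        return len(self.ids)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def load(self, indices) -> np.ndarray:
        return self.images[np.asarray(indices)]


class ImageFolderDataset:
    """Raster files (PNG/JPEG/TIFF) under a root, listed by a manifest CSV.

    Images are resized to a square ``image_side`` (bilinear) at load time
    and scaled to [0, 1].  ``strict`` controls whether an unreadable file
    aborts (default) or is skipped with a log line at construction.
    """

    def __init__(self, manifest_path: str | Path, image_side: int = 224,
                 strict: bool = True):
        self.root = Path(manifest_path).parent
        self.manifest = load_manifest(manifest_path)
        self.image_side = int(image_side)
        if self.image_side % 32:
            raise ValueError(f"image_side {image_side} not divisible by 32")
        self.strict = strict
        if len(self.manifest) == 0:
            raise ValueError("empty dataset")
        self.ids = list(self.manifest["id"])
        self.labels = np.asarray(self.manifest["class"], dtype=np.int64)
        self.scans = list(self.manifest["scan"])

    @property
    def n_images(self) -> int:
        return len(self.ids)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def load(self, indices) -> np.ndarray:
        from PIL import Image

        out = np.zeros(
            (len(indices), self.image_side, self.image_side, 3), dtype=np.float64
        )
        for row, i in enumerate(np.asarray(indices)):
            path = self.root / self.manifest["path"].iloc[int(i)]
            try:
                with Image.open(path) as im:
                    im = im.convert("RGB").resize(
                        (self.image_side, self.image_side), Image.BILINEAR
                    )
                    out[row] = np.asarray(im, dtype=np.float64) / 255.0
            except OSError as exc:
                if self.strict:
                    raise OSError(f"unreadable image {path}") from exc
                import logging

                logging.getLogger(__name__).warning("skipping %s: %s", path, exc)
        return out
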