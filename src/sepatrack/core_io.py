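"""Shared domain types, frame/label-map I/O, run configuration and logging.

The pipeline operates on fixed-camera recordings of an arena containing
exactly two visually identical animals.  All image data is exchanged as
numpy arrays using the row-major ``(row, col)`` convention with 0-based
indices; the thin dataclasses below add provenance (frame index, mask role,
the "unseparated" flag) on top of the raw arrays.

Label maps use the fixed convention ``0 = background``, ``1`` and ``2`` for
the two instances, and are stored as indexed PNGs with the palette
0→black, 1→red, 2→green so they are inspectable in any image viewer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "Frame",
    "BinaryMask",
    "LabelMap",
    "EdgeImage",
    "PipelineConfig",
    "RunLog",
    "read_sequence",
    "write_label_map",
    "read_label_map",
    "write_frame",
]

LABEL_PALETTE = {0: (0, 0, 0), 1: (255, 0, 0), 2: (0, 128, 0)}

_FRAME_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One RGB image of the arena at a given time index."""

    pixels: np.ndarray  # H x W x 3, uint8
    index: int
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:  # tolerate grayscale input, promote to RGB
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"frame pixels must be H x W x 3, got {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"frame too small: {px.shape[:2]} (minimum 32 x 32)")
        self.pixels = np.ascontiguousarray(px, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def gray(self) -> np.ndarray:
        """Luma grayscale in [0, 255] as float64."""
        return self.pixels.astype(np.float64) @ np.array([0.299, 0.587, 0.114])


@dataclass
class BinaryMask:
    """Boolean pixel mask with a role tag (foreground, boundary, ...)."""

    pixels: np.ndarray  # H x W, bool
    role: str = "foreground"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class LabelMap:
    """Per-pixel instance labels in {0, 1, 2} plus the unseparated flag.

    ``unseparated`` marks frames where the segmentation could not split a
    single connected foreground region into two instances; such maps carry
    no identity claim.
    """

    labels: np.ndarray  # H x W, uint8 in {0, 1, 2}
    unseparated: bool = False

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label map must be 2-D")
        bad = np.setdiff1d(np.unique(lab), [0, 1, 2])
        if bad.size:
            raise ValueError(f"labels outside {{0,1,2}}: {bad.tolist()}")
        self.labels = lab.astype(np.uint8)

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class EdgeImage:
    """Grayscale edge-intensity map in [0, 255]."""

    intensities: np.ndarray  # H x W, float in [0, 255]
    provenance: str = "detector"  # detector | completed | ground-truth

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("edge image must be 2-D")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError("edge intensities must lie in [0, 255]")
        self.intensities = arr


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with their defaults.

    The edge threshold ``theta`` is on the [0, 255] intensity scale; radii
    and kernel sizes are in pixels.  Every source of randomness derives
    from ``seed`` through named substreams (see :meth:`rng`) so a run is
    fully reproducible from its config.
    """

    # edge thresholding
    theta: float = 60.0
    # augmentation
    inpaint_radius: int = 7
    crop_size: int = 256
    rotation_count: int = 5
    translation_count: int = 2
    rotation_jitter_deg: float = 15.0
    disjoint_fraction: float = 0.2
    aGT_thickness: int = 1
    # background / foreground
    background_samples: int = 2000
    fg_diff_threshold: float = 30.0
    fg_min_area_frac: float = 0.001
    fg_morph_radius: int = 2
    tail_opening_radius: int = 3
    # segmentation morphology
    edge_closing_radius: int = 2
    midline_dilation: int = 1
    s_dilation_radius: int = 2
    # edge providers
    edge_provider: str = "canny"
    canny_low: float = 40.0
    canny_high: float = 120.0
    # tracking rule filter
    area_ratio_low: float = 0.3
    area_ratio_high: float = 3.0
    # evaluation
    boundary_tol_frac: float = 0.008
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.theta <= 255:
            raise ValueError("theta must lie in [0, 255]")
        for name in ("inpaint_radius", "crop_size", "background_samples",
                     "rotation_count", "translation_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    # -- named substreams ---------------------------------------------------
    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-module random generator derived from the seed."""
        digest = hashlib.sha256(stream.encode()).digest()
        sub = int.from_bytes(digest[:4], "big") % (2 ** 31)
        return np.random.default_rng([int(self.seed) % (2 ** 31), sub])

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


class RunLog:
    """Minimal JSON-lines run log."""

    def __init__(self, path: Optional[str | Path] = None):
        self.path = Path(path) if path is not None else None
        self.records: list[dict] = []

    def log(self, event: str, **fields) -> None:
        rec = {"time": time.time(), "event": event, **fields}
        self.records.append(rec)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Sequence and label-map I/O
# ---------------------------------------------------------------------------

def _natural_key(name: str):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name)]


def read_sequence(path: str | Path) -> list[Frame]:
    """Read an ordered frame sequence from a directory or video file.

    Directories are scanned for image files and sorted by natural filename
    order; every frame must share the same height and width.  Video
    containers are decoded through imageio when a suitable plugin is
    available.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such input: {path}")
    images: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise IOError(f"no frames found in {path}")
        for p in files:
            images.append(np.asarray(Image.open(p).convert("RGB")))
    else:
        import imageio.v2 as iio

        try:
            reader = iio.get_reader(path)
            images = [np.asarray(im)[..., :3] for im in reader]
        except Exception as exc:  # pragma: no cover - backend dependent
            raise IOError(f"cannot decode video {path}: {exc}") from exc
        if not images:
            raise IOError(f"no frames found in {path}")
    shape = images[0].shape[:2]
    for i, im in enumerate(images):
        if im.shape[:2] != shape:
            raise ValueError(
                f"inconsistent frame dimensions: frame {i} is {im.shape[:2]}, "
                f"expected {shape}"
            )
    return [Frame(pixels=im, index=i) for i, im in enumerate(images)]


def write_frame(frame: Frame | np.ndarray, path: str | Path) -> None:
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, np.uint8)
    Image.fromarray(px).save(path)


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    """Write a label map as an indexed PNG plus a JSON metadata sidecar."""
    path = Path(path)
    lab = label_map.labels
    img = Image.fromarray(lab, mode="P")
    palette = []
    for i in range(256):
        palette.extend(LABEL_PALETTE.get(i, (0, 0, 0)))
    img.putpalette(palette)
    img.save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"unseparated": bool(label_map.unseparated)}))


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    img = Image.open(path)
    lab = np.asarray(img, dtype=np.uint8)
    sidecar = path.with_suffix(path.suffix + ".json")
    unseparated = False
    if sidecar.exists():
        unseparated = bool(json.loads(sidecar.read_text()).get("unseparated", False))
    return LabelMap(labels=lab, unseparated=unseparated)
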