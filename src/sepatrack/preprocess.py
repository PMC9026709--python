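"""Background estimation, foreground extraction and instance labelling.

With a fixed camera and a static arena, the background is recovered as the
per-pixel temporal mode of a sample of frames; the foreground follows by
background subtraction with a per-frame gain normalisation that absorbs
global illumination changes.  Tails are removed by binary opening before
instance labelling because their thin, fast-changing shapes carry no
information for body segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from skimage import morphology

from .core_io import BinaryMask, EdgeImage, Frame, LabelMap, PipelineConfig

__all__ = [
    "BackgroundModel",
    "estimate_background",
    "extract_foreground",
    "remove_tails",
    "label_instances",
    "make_edge_mask",
]


@dataclass
class BackgroundModel:
    """Static background image plus the medians used for gain normalisation."""

    background: np.ndarray  # H x W x 3, uint8
    median: float  # scalar median intensity of the background image

    @property
    def shape(self) -> tuple[int, int]:
        return self.background.shape[:2]


def _frame_pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, Frame) else np.asarray(frame)


def estimate_background(frames: Sequence, n: Optional[int] = None) -> BackgroundModel:
    """Per-pixel, per-channel temporal mode of ``n`` uniformly sampled frames.

    Intensities are binned at integer width 1 (they are 8-bit already); ties
    between equally frequent values resolve to the lowest intensity, which
    makes the estimate deterministic.
    """
    if len(frames) == 0:
        raise ValueError("cannot estimate a background from zero frames")
    if n is None:
        n = len(frames)
    if not 1 <= n <= len(frames):
        raise ValueError(f"need 1 <= n <= {len(frames)}, got {n}")
    idx = np.unique(np.linspace(0, len(frames) - 1, n).round().astype(int))
    stack = np.stack([_frame_pixels(frames[i]) for i in idx])
    # scipy's mode returns the smallest value among ties
    mode = stats.mode(stack, axis=0, keepdims=False).mode.astype(np.uint8)
    return BackgroundModel(background=mode, median=float(np.median(mode)))


def extract_foreground(
    frame,
    bg: BackgroundModel,
    cfg: Optional[PipelineConfig] = None,
    *,
    diff_threshold: Optional[float] = None,
    min_area_frac: Optional[float] = None,
    morph_radius: Optional[int] = None,
) -> BinaryMask:
    """Foreground mask F by gain-normalised background subtraction.

    The frame is first rescaled by the ratio of the background median to the
    frame median (an intensity-histogram robustification against global
    illumination shifts and reflections), then pixels whose maximum absolute
    channel difference from the background exceeds ``diff_threshold`` are
    kept.  Morphological opening and closing (disk of ``morph_radius``)
    clean speckle, and connected components smaller than
    ``min_area_frac`` of the image are dropped.
    """
    cfg = cfg or PipelineConfig()
    diff_threshold = cfg.fg_diff_threshold if diff_threshold is None else diff_threshold
    min_area_frac = cfg.fg_min_area_frac if min_area_frac is None else min_area_frac
    morph_radius = cfg.fg_morph_radius if morph_radius is None else morph_radius

    px = _frame_pixels(frame).astype(np.float64)
    if px.shape[:2] != bg.shape:
        raise ValueError("frame and background shapes differ")
    frame_median = float(np.median(px))
    gain = bg.median / frame_median if frame_median > 0 else 1.0
    diff = np.abs(px * gain - bg.background.astype(np.float64)).max(axis=2)
    mask = diff > diff_threshold
    if morph_radius > 0:
        disk = morphology.disk(morph_radius)
        mask = morphology.opening(mask, disk)
        mask = morphology.closing(mask, disk)
    min_area = int(round(min_area_frac * mask.size))
    if min_area > 1:
        # strictly-smaller removal: components of exactly min_area survive
        mask = morphology.remove_small_objects(
            mask, max_size=min_area - 1, connectivity=2)
    return BinaryMask(pixels=mask, role="foreground")


def remove_tails(F, radius: int = 3) -> BinaryMask:
    """Binary opening with a disk: erases protrusions thinner than the disk.

    Opening is anti-extensive, so no pixel is ever added.
    """
    mask = F.pixels if isinstance(F, BinaryMask) else np.asarray(F, bool)
    if radius <= 0:
        return BinaryMask(pixels=mask.copy(), role="foreground")
    opened = morphology.opening(mask, morphology.disk(radius))
    return BinaryMask(pixels=opened, role="foreground")


def label_instances(F) -> tuple[LabelMap, bool]:
    """Label the two largest 8-connected foreground components.

    Returns ``(label_map, occluding)``: with two or more components the two
    largest become labels 1 (bigger) and 2 (smaller) and ``occluding`` is
    False; a single component means the animals touch — it becomes label 1
    with the map flagged unseparated and ``occluding`` True.
    """
    mask = F.pixels if isinstance(F, BinaryMask) else np.asarray(F, bool)
    from skimage import measure

    comp = measure.label(mask, connectivity=2)
    ncomp = comp.max()
    labels = np.zeros(mask.shape, dtype=np.uint8)
    if ncomp == 0:
        return LabelMap(labels=labels, unseparated=True), False
    areas = np.bincount(comp.ravel())[1:]
    order = np.argsort(areas, kind="stable")[::-1] + 1
    if ncomp == 1:
        labels[comp == order[0]] = 1
        return LabelMap(labels=labels, unseparated=True), True
    labels[comp == order[0]] = 1
    labels[comp == order[1]] = 2
    return LabelMap(labels=labels, unseparated=False), False


def make_edge_mask(F, E, dilation_radius: int = 2) -> EdgeImage:
    """Zero an edge image outside the dilated foreground mask.

    Edge detectors respond to arena furniture and reflections well outside
    the animals; masking with a slightly dilated foreground keeps the
    instance contours (which straddle the mask border) while discarding the
    rest.
    """
    mask = F.pixels if isinstance(F, BinaryMask) else np.asarray(F, bool)
    edges = E.intensities if isinstance(E, EdgeImage) else np.asarray(E, np.float64)
    if dilation_radius > 0:
        mask = morphology.dilation(mask, morphology.disk(dilation_radius))
    out = np.where(mask, edges, 0.0)
    prov = E.provenance if isinstance(E, EdgeImage) else "detector"
    return EdgeImage(intensities=out, provenance=prov)
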