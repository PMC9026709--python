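"""Edge detection providers, inpaint masks, completion loss and fallback.

Edge detection is pluggable: anything mapping a frame (plus an optional
foreground mask) to a [0, 255] edge-intensity image can drive the
segmentation stage.  The default provider is Canny.  For occluding frames
whose separating edge is broken, :func:`complete_edges_fallback` bridges
skeleton endpoints inside the foreground with minimal-cost paths — a
deterministic realisation of edge completion that keeps the downstream
segmentation testable without any trained model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage import feature, graph, morphology

from .core_io import BinaryMask, EdgeImage, Frame, PipelineConfig, RunLog

__all__ = [
    "EdgeProvider",
    "CompletionContext",
    "get_provider",
    "detect_edges_canny",
    "binarize_boundary",
    "compute_inpaint_mask",
    "completion_loss",
    "weight_for_discriminator",
    "complete_edges_fallback",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class EdgeProvider:
    """Named edge detector with a ``predict(frame, foreground=None)`` contract.

    The output must share the frame's height/width with values in [0, 255].
    """

    name: str
    predict: Callable[..., EdgeImage]


@dataclass
class CompletionContext:
    """Masks and normalised edge images entering the completion loss.

    ``M = F \\ B`` is the inpaint mask: the foreground minus the known
    boundary, i.e. the region where missing edges must be synthesised.
    ``S`` emphasises the separating edge.  ``Epred``/``EaGT`` are on [0, 1].
    """

    F: np.ndarray
    B: np.ndarray
    M: np.ndarray
    S: np.ndarray
    Epred: np.ndarray
    EaGT: np.ndarray


def _gray(frame) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.gray()
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr @ np.array([0.299, 0.587, 0.114])
    return arr


def _edges(E) -> np.ndarray:
    return E.intensities if isinstance(E, EdgeImage) else np.asarray(E, np.float64)


def _mask(m) -> np.ndarray:
    return m.pixels if isinstance(m, BinaryMask) else np.asarray(m, bool)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_edges_canny(frame, low: float = 40.0, high: float = 120.0,
                       sigma: float = 1.4) -> EdgeImage:
    """Canny edges on the grayscale frame, scaled to {0, 255}."""
    if not 0 <= low <= high <= 255:
        raise ValueError("need 0 <= low <= high <= 255")
    gray = _gray(frame)
    binary = feature.canny(gray, sigma=sigma, low_threshold=low, high_threshold=high)
    return EdgeImage(intensities=binary.astype(np.float64) * 255.0,
                     provenance="detector")


def get_provider(cfg: Optional[PipelineConfig] = None) -> EdgeProvider:
    """Resolve the configured edge provider."""
    cfg = cfg or PipelineConfig()
    name = cfg.edge_provider
    if name == "canny":
        def predict(frame, foreground=None):
            return detect_edges_canny(frame, cfg.canny_low, cfg.canny_high)
        return EdgeProvider(name="canny", predict=predict)
    raise ValueError(f"unknown edge provider: {name!r}")


# ---------------------------------------------------------------------------
# Masks and loss
# ---------------------------------------------------------------------------

def binarize_boundary(E, theta_b: float) -> BinaryMask:
    """Boundary mask B = {p : E(p) > theta_b} (strict inequality)."""
    if not 0 <= theta_b <= 255:
        raise ValueError("theta_b must lie in [0, 255]")
    return BinaryMask(pixels=_edges(E) > theta_b, role="boundary")


def compute_inpaint_mask(F, B) -> BinaryMask:
    """Inpaint mask M = F \\ B (set difference), the region of missing edges."""
    f, b = _mask(F), _mask(B)
    if f.shape != b.shape:
        raise ValueError("mask shapes differ")
    return BinaryMask(pixels=f & ~b, role="inpaint")


def _masked_bce(pred: np.ndarray, target: np.ndarray, mask: np.ndarray,
                eps: float = 1e-7) -> float:
    sel = mask > 0
    if not sel.any():
        return 0.0
    p = np.clip(pred[sel], eps, 1 - eps)
    t = target[sel]
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


def completion_loss(ctx: CompletionContext) -> float:
    """Two-term completion loss: masked BCE over the inpaint region plus
    masked BCE over the (dilated) separating-edge region.

    Each term is the mean binary cross-entropy over the pixels where its
    mask is nonzero (0 for an empty mask), with predictions clipped to
    ``[1e-7, 1 - 1e-7]``.
    """
    for name in ("Epred", "EaGT"):
        arr = getattr(ctx, name)
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    return (_masked_bce(ctx.Epred, ctx.EaGT, np.asarray(ctx.M))
            + _masked_bce(ctx.Epred, ctx.EaGT, np.asarray(ctx.S)))


def weight_for_discriminator(E, upper_contour) -> EdgeImage:
    """Down-weight edges that do not belong to the upper instance.

    Edge pixels on the upper instance's contour keep their intensity; all
    other pixels are halved, emphasising the closedness of the upper
    contour in discrimination.
    """
    e = _edges(E)
    up = _mask(upper_contour)
    if e.shape != up.shape:
        raise ValueError("shapes differ")
    out = np.where(up, e, 0.5 * e)
    prov = E.provenance if isinstance(E, EdgeImage) else "detector"
    return EdgeImage(intensities=out, provenance=prov)


# ---------------------------------------------------------------------------
# Deterministic completion fallback
# ---------------------------------------------------------------------------

def _skeleton_endpoints(skel: np.ndarray) -> np.ndarray:
    neigh = ndimage.convolve(skel.astype(np.uint8), _SQUARE3.astype(np.uint8),
                             mode="constant") - skel.astype(np.uint8)
    return np.argwhere(skel & (neigh == 1))


def complete_edges_fallback(E, F, theta: float = 60.0,
                            log: Optional[RunLog] = None) -> EdgeImage:
    """Bridge gaps in the separating edge with minimal-cost paths.

    The thresholded edges are skeletonised; skeleton endpoints strictly
    inside the foreground are candidate gap ends.  Endpoint pairs are
    joined greedily by ascending path cost, where each pixel costs
    ``1 + (255 - E(p)) / 255`` and paths may not leave the foreground nor
    cross its 1-px external boundary.  Bridged paths are drawn into the
    edge image at intensity 255.  Existing edge pixels are never lowered
    and nothing outside the foreground is modified.
    """
    e = _edges(E).copy()
    f = _mask(F)
    binary = e > theta
    skel = morphology.skeletonize(binary)
    ext_boundary = f & ~ndimage.binary_erosion(f, structure=_SQUARE3)
    interior = f & ~ext_boundary
    endpoints = [tuple(p) for p in _skeleton_endpoints(skel) if interior[tuple(p)]]
    if len(endpoints) < 2:
        (log or RunLog()).log("edge_completion_no_endpoints", found=len(endpoints))
        prov = E.provenance if isinstance(E, EdgeImage) else "detector"
        return EdgeImage(intensities=e, provenance=prov)

    allowed = interior.copy()
    for p in endpoints:
        allowed[p] = True
    costs = np.where(allowed, 1.0 + (255.0 - e) / 255.0, np.inf)

    pairs = []
    for i in range(len(endpoints)):
        for j in range(i + 1, len(endpoints)):
            try:
                path, cost = graph.route_through_array(
                    costs, endpoints[i], endpoints[j],
                    fully_connected=True, geometric=True)
            except ValueError:
                continue
            if np.isfinite(cost):
                pairs.append((cost, i, j, path))
    pairs.sort(key=lambda t: t[0])
    used: set[int] = set()
    for cost, i, j, path in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        for (r, c) in path:
            e[r, c] = 255.0
    prov = "completed"
    return EdgeImage(intensities=e, provenance=prov)
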