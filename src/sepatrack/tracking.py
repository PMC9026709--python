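"""Temporal identity propagation over per-frame segmentations.

Identities are anchored at the first frame whose segmentation passes a
rule-based preservation filter.  From each preserved frame the two ID
masks are warped forward frame-by-frame with dense optical flow; at the
next preserved frame the warped masks guide a bipartite matching (maximum
total IoU) that relabels the original per-frame prediction, and the warp
restarts from there — successive warping is never allowed to accumulate
across more than one preserved-to-preserved span, because repeated
pixel-wise warping smears masks over long time ranges.  Frames that fail
the filter only receive the warped masks as provisional output, clearly
marked, and never anchor identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.registration import optical_flow_ilk

from .core_io import BinaryMask, Frame, LabelMap, PipelineConfig
from .segmentation import correct_body_overlap

__all__ = [
    "TrackRecord",
    "compute_flow",
    "warp_mask",
    "rule_filter",
    "bipartite_match",
    "propagate_ids",
]


@dataclass
class TrackRecord:
    """ID-consistent per-frame label maps with provenance.

    ``status[t]`` is ``preserved`` (original prediction, relabelled to the
    global IDs), ``propagated`` (warped reference masks only — provisional)
    or ``flagged`` (the per-frame segmentation failed; the warped masks are
    carried but make no identity claim).  ``reference[t]`` is the preserved
    frame whose masks guided frame ``t``.
    """

    maps: list[LabelMap]
    status: list[str]
    reference: list[int]
    anchor: int

    def __len__(self) -> int:
        return len(self.maps)


def _gray(frame) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.gray()
    arr = np.asarray(frame, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr @ np.array([0.299, 0.587, 0.114])
    return arr


def compute_flow(frameA, frameB, radius: int = 7) -> np.ndarray:
    """Dense optical flow from frame A to frame B (H x W x 2, px).

    ``flow[r, c]`` is the displacement of the content at ``(r, c)`` in A to
    its position in B, estimated with the iterative Lucas-Kanade solver.
    Deterministic given its inputs.
    """
    g0 = _gray(frameA)
    g1 = _gray(frameB)
    if g0.shape != g1.shape:
        raise ValueError("frame shapes differ")
    flow = optical_flow_ilk(g0, g1, radius=radius)
    return np.moveaxis(flow, 0, -1)


def warp_mask(mask, flow: np.ndarray) -> BinaryMask:
    """Shift each foreground pixel by its rounded flow vector.

    Collisions keep the pixel (logical OR); pixels leaving the image are
    dropped.
    """
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if flow.shape[:2] != m.shape:
        raise ValueError("flow and mask shapes differ")
    H, W = m.shape
    rows, cols = np.nonzero(m)
    out = np.zeros_like(m)
    if rows.size:
        nr = rows + np.rint(flow[rows, cols, 0]).astype(int)
        nc = cols + np.rint(flow[rows, cols, 1]).astype(int)
        keep = (nr >= 0) & (nr < H) & (nc >= 0) & (nc < W)
        out[nr[keep], nc[keep]] = True
    return BinaryMask(out, role="foreground")


def rule_filter(
    label_map: LabelMap,
    median_area: Optional[float] = None,
    cfg: Optional[PipelineConfig] = None,
) -> bool:
    """Decide whether a per-frame segmentation is reliable enough to anchor
    identity propagation.

    Preserved frames must be unflagged, contain both instance labels, and
    have each instance area within ``[area_ratio_low, area_ratio_high]``
    times the running median instance area (vacuously true while no
    history exists).
    """
    cfg = cfg or PipelineConfig()
    if label_map.unseparated:
        return False
    if set(label_map.present_labels()) != {1, 2}:
        return False
    if median_area is None or median_area <= 0:
        return True
    for lab in (1, 2):
        area = int((label_map.labels == lab).sum())
        if not cfg.area_ratio_low * median_area <= area <= cfg.area_ratio_high * median_area:
            return False
    return True


def bipartite_match(scores: np.ndarray) -> tuple[int, ...]:
    """Permutation maximising the total score of an n x n IoU matrix.

    ``perm[i] = j`` assigns row (reference identity) ``i`` to column
    (current instance) ``j``.  For two instances both permutations are
    compared directly; ties resolve to the identity permutation.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("score matrix must be square")
    n = s.shape[0]
    if n == 2:
        keep = s[0, 0] + s[1, 1]
        swap = s[0, 1] + s[1, 0]
        return (0, 1) if keep >= swap else (1, 0)
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-s)
    best = s[rows, cols].sum()
    if s.trace() >= best - 1e-12:
        return tuple(range(n))
    return tuple(int(c) for c in cols[np.argsort(rows)])


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum()) / union if union else 1.0


def _provisional(w1: np.ndarray, w2: np.ndarray, flagged: bool) -> LabelMap:
    """Label map from warped reference masks; overlaps split by centroid."""
    if w1.any() and w2.any():
        m1, m2 = correct_body_overlap(w1, w2)
        w1, w2 = m1.pixels, m2.pixels
    labels = np.zeros(w1.shape, dtype=np.uint8)
    labels[w1] = 1
    labels[w2] = 2
    return LabelMap(labels=labels, unseparated=flagged)


def propagate_ids(
    maps: Sequence[LabelMap],
    frames: Sequence,
    cfg: Optional[PipelineConfig] = None,
) -> TrackRecord:
    """Propagate consistent instance IDs across per-frame segmentations.

    The first preserved frame fixes the identities.  Warped reference
    masks only guide the matching — preserved frames keep their original
    segmentation geometry, merely relabelled.
    """
    cfg = cfg or PipelineConfig()
    if len(maps) != len(frames):
        raise ValueError("maps and frames must align")
    n = len(maps)
    status: list[str] = ["flagged"] * n
    reference = [-1] * n
    out: list[Optional[LabelMap]] = [None] * n
    area_history: list[float] = []

    def running_median() -> Optional[float]:
        return float(np.median(area_history)) if area_history else None

    # forward scan: preservation decisions use only past history
    anchor = -1
    ref_idx = -1
    ref1 = ref2 = None  # warped reference masks, current-frame coordinates
    for t in range(n):
        m = maps[t]
        if anchor >= 0 and t > 0:
            flow = compute_flow(frames[t - 1], frames[t])
            ref1 = warp_mask(ref1, flow).pixels
            ref2 = warp_mask(ref2, flow).pixels
        if rule_filter(m, running_median(), cfg):
            if anchor < 0:
                anchor = t
                relabelled = m
            else:
                cur = [m.labels == 1, m.labels == 2]
                scores = np.array([[_mask_iou(ref1, cur[0]), _mask_iou(ref1, cur[1])],
                                   [_mask_iou(ref2, cur[0]), _mask_iou(ref2, cur[1])]])
                perm = bipartite_match(scores)
                labels = np.zeros_like(m.labels)
                labels[cur[perm[0]]] = 1
                labels[cur[perm[1]]] = 2
                relabelled = LabelMap(labels=labels, unseparated=False)
            out[t] = relabelled
            status[t] = "preserved"
            reference[t] = ref_idx if ref_idx >= 0 else t
            ref_idx = t
            ref1 = relabelled.labels == 1
            ref2 = relabelled.labels == 2
            for lab in (1, 2):
                area_history.append(float((relabelled.labels == lab).sum()))
        elif anchor >= 0:
            out[t] = _provisional(ref1, ref2, m.unseparated)
            status[t] = "flagged" if m.unseparated else "propagated"
            reference[t] = ref_idx
    if anchor < 0:
        raise RuntimeError("no reliable frame to anchor identities")

    # backward fill for frames before the anchor
    ref1 = maps[anchor].labels == 1
    ref2 = maps[anchor].labels == 2
    for t in range(anchor - 1, -1, -1):
        flow = compute_flow(frames[t + 1], frames[t])
        ref1 = warp_mask(ref1, flow).pixels
        ref2 = warp_mask(ref2, flow).pixels
        out[t] = _provisional(ref1, ref2, maps[t].unseparated)
        status[t] = "flagged" if maps[t].unseparated else "propagated"
        reference[t] = anchor
    return TrackRecord(maps=list(out), status=status, reference=reference,
                       anchor=anchor)
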