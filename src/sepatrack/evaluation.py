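"""Evaluation metrics: region IoU, boundary F-score, track switches.

Per-frame segmentation quality is measured with the Jaccard index (IoU);
because per-frame predictions carry no identities, frame-level IoU takes
the maximum over both label assignments.  Boundary quality follows the
video-object-segmentation convention: precision/recall between contour
pixel sets within a pixel tolerance, combined as F = 2PR/(P+R).  Tracking
quality is the number of identity switches (flips of the IoU-optimal
prediction-to-ground-truth permutation between consecutive scored frames)
and the number of frames with fewer than two distinct instance labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import morphology

from .core_io import BinaryMask, LabelMap, PipelineConfig
from .tracking import TrackRecord, bipartite_match

__all__ = [
    "EvalReport",
    "iou",
    "frame_iou_best_assignment",
    "boundary_prf",
    "count_track_switches",
    "count_lost_id_frames",
    "boundary_of",
    "evaluate_sequence",
]


@dataclass
class EvalReport:
    """Aggregate metrics of one sequence."""

    per_frame_iou: list[float]
    iou_mean: float
    f_mean: float
    precision_mean: float
    recall_mean: float
    track_switches: int
    lost_id_frames: int
    unseparated_frames: int

    def to_dict(self) -> dict:
        return {
            "iou_mean": self.iou_mean,
            "f_mean": self.f_mean,
            "precision_mean": self.precision_mean,
            "recall_mean": self.recall_mean,
            "track_switches": self.track_switches,
            "lost_id_frames": self.lost_id_frames,
            "unseparated_frames": self.unseparated_frames,
            "per_frame_iou": self.per_frame_iou,
        }


def _mask(m) -> np.ndarray:
    return m.pixels if isinstance(m, BinaryMask) else np.asarray(m, bool)


def iou(P, G) -> float:
    """Jaccard index |P ∩ G| / |P ∪ G|; 1.0 when both masks are empty."""
    p, g = _mask(P), _mask(G)
    if p.shape != g.shape:
        raise ValueError("mask shapes differ")
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return float((p & g).sum()) / union


def frame_iou_best_assignment(pred: LabelMap, gt: LabelMap,
                              remove_tails: bool = False,
                              tail_radius: int = 3) -> float:
    """Mean instance IoU under the better of the two label assignments.

    Per-frame predictions have no identities, so both pairings
    (1↔1, 2↔2) and (1↔2, 2↔1) are scored and the maximum returned.  With
    ``remove_tails`` each instance mask of both maps is opened with a disk
    first, so thin tails do not dominate the comparison.
    """
    def inst(m: LabelMap, lab: int) -> np.ndarray:
        mask = m.labels == lab
        if remove_tails and mask.any():
            mask = morphology.opening(mask, morphology.disk(tail_radius))
        return mask

    p = {lab: inst(pred, lab) for lab in (1, 2)}
    g = {lab: inst(gt, lab) for lab in (1, 2)}
    present = [lab for lab in (1, 2) if g[lab].any()]
    if not present:
        warnings.warn("ground truth contains no instances")
        return 1.0
    if len(present) == 1:
        warnings.warn("ground truth missing an instance; scoring the other only")
        lab = present[0]
        return max(iou(p[1], g[lab]), iou(p[2], g[lab]))
    straight = (iou(p[1], g[1]) + iou(p[2], g[2])) / 2
    swapped = (iou(p[1], g[2]) + iou(p[2], g[1])) / 2
    return max(straight, swapped)


def boundary_of(mask) -> np.ndarray:
    """1-px inner contour of a mask (8-connectivity)."""
    m = _mask(mask)
    from scipy import ndimage
    return m & ~ndimage.binary_erosion(m, structure=np.ones((3, 3), bool))


def boundary_prf(predB, gtB, tol: float = 0.0) -> tuple[float, float, float]:
    """Boundary F-measure with a pixel tolerance.

    P is the fraction of predicted contour pixels within Euclidean
    distance ``tol`` of the ground-truth contour (via dilation), R the
    symmetric quantity, and F = 2PR/(P+R) (0 when P + R = 0).  Returns
    ``(F, P, R)``.
    """
    pb, gb = _mask(predB), _mask(gtB)
    if tol > 0:
        disk = morphology.disk(int(round(tol)))
        gb_tol = morphology.dilation(gb, disk)
        pb_tol = morphology.dilation(pb, disk)
    else:
        gb_tol, pb_tol = gb, pb
    n_pred = int(pb.sum())
    n_gt = int(gb.sum())
    P = float((pb & gb_tol).sum()) / n_pred if n_pred else 0.0
    R = float((gb & pb_tol).sum()) / n_gt if n_gt else 0.0
    F = 2 * P * R / (P + R) if (P + R) > 0 else 0.0
    return F, P, R


def _frame_permutation(pred: LabelMap, gt: LabelMap) -> tuple[int, ...]:
    pm = [pred.labels == 1, pred.labels == 2]
    gm = [gt.labels == 1, gt.labels == 2]
    scores = np.array([[iou(gm[i], pm[j]) for j in range(2)] for i in range(2)])
    return bipartite_match(scores)


def count_track_switches(track: TrackRecord | Sequence[LabelMap],
                         gt_maps: Sequence[LabelMap]) -> int:
    """Number of identity switches against ID-consistent ground truth.

    For every unflagged frame holding both labels, the IoU-optimal
    permutation between prediction and ground truth is computed; a switch
    is a frame where this permutation differs from the one at the previous
    scored frame.  Flagged and lost-ID frames are skipped without
    resetting the previous permutation, so a swap hiding behind an
    occlusion gap is still counted.
    """
    maps = track.maps if isinstance(track, TrackRecord) else list(track)
    if len(maps) != len(gt_maps):
        raise ValueError("prediction and ground truth lengths differ")
    prev: Optional[tuple[int, ...]] = None
    switches = 0
    for pred, gt in zip(maps, gt_maps):
        if pred.unseparated or set(pred.present_labels()) != {1, 2}:
            continue
        perm = _frame_permutation(pred, gt)
        if prev is not None and perm != prev:
            switches += 1
        prev = perm
    return switches


def count_lost_id_frames(maps: Sequence[LabelMap]) -> int:
    """Frames whose map holds fewer than two distinct nonzero labels
    (flagged frames included)."""
    return sum(1 for m in maps if len(m.present_labels()) < 2)


def evaluate_sequence(
    track: TrackRecord | Sequence[LabelMap],
    gt_maps: Sequence[LabelMap],
    cfg: Optional[PipelineConfig] = None,
    remove_tails: bool = False,
) -> EvalReport:
    """Full report for a tracked sequence against ground truth."""
    cfg = cfg or PipelineConfig()
    maps = track.maps if isinstance(track, TrackRecord) else list(track)
    if len(maps) != len(gt_maps):
        raise ValueError("prediction and ground truth lengths differ")
    H, W = maps[0].labels.shape if maps else (0, 0)
    tol = cfg.boundary_tol_frac * np.hypot(H, W)
    per_iou: list[float] = []
    Ps, Rs, Fs = [], [], []
    for pred, gt in zip(maps, gt_maps):
        per_iou.append(frame_iou_best_assignment(pred, gt, remove_tails))
        perm = _frame_permutation(pred, gt)
        fs, ps, rs = [], [], []
        for i, lab in enumerate((1, 2)):
            gb = boundary_of(gt.labels == lab)
            pb = boundary_of(pred.labels == perm[i] + 1)
            F, P, R = boundary_prf(pb, gb, tol)
            fs.append(F); ps.append(P); rs.append(R)
        Fs.append(float(np.mean(fs)))
        Ps.append(float(np.mean(ps)))
        Rs.append(float(np.mean(rs)))
    unsep = sum(1 for m in maps if m.unseparated)
    return EvalReport(
        per_frame_iou=per_iou,
        iou_mean=float(np.mean(per_iou)) if per_iou else 0.0,
        f_mean=float(np.mean(Fs)) if Fs else 0.0,
        precision_mean=float(np.mean(Ps)) if Ps else 0.0,
        recall_mean=float(np.mean(Rs)) if Rs else 0.0,
        track_switches=count_track_switches(track, gt_maps),
        lost_id_frames=count_lost_id_frames(maps),
        unseparated_frames=unsep,
    )
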