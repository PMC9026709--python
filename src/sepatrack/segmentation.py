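"""Per-frame instance segmentation from edges and body regions.

For occluding frames the foreground is a single connected region; the
(completed) edge image is thresholded, closed and skeletonised into a
midline that carves the foreground into edge regions.  These are combined
with up to two predicted body regions by overlap ratio to build initial
markers, from which a marker-controlled watershed over the edge-intensity
landscape fills the foreground and yields the two instances.  When the
edge structure cannot split the foreground, the frame is flagged
unseparated rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation as sk_seg

from .core_io import BinaryMask, EdgeImage, Frame, LabelMap, PipelineConfig
from .edge_models import complete_edges_fallback
from .preprocess import label_instances, remove_tails

__all__ = [
    "EdgeRegions",
    "BodyRegions",
    "find_edge_regions",
    "correct_body_overlap",
    "assign_regions",
    "watershed_fill",
    "segment_frame",
]


@dataclass
class EdgeRegions:
    """Foreground partition induced by the edge midline."""

    regions: np.ndarray  # H x W int, 0 = none, 1..L sorted by descending area
    L: int
    midline: BinaryMask  # the dilated midline that bounds the regions


@dataclass
class BodyRegions:
    """Up to two body masks with their centroids (row, col)."""

    masks: list[np.ndarray]
    centroids: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m, bool) for m in self.masks if np.asarray(m).any()]
        if not self.centroids:
            self.centroids = [_centroid(m) for m in self.masks]


def _centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def _mask(m) -> np.ndarray:
    return m.pixels if isinstance(m, BinaryMask) else np.asarray(m, bool)


def _edges(E) -> np.ndarray:
    return E.intensities if isinstance(E, EdgeImage) else np.asarray(E, np.float64)


# ---------------------------------------------------------------------------
# Edge regions
# ---------------------------------------------------------------------------

def find_edge_regions(G, F, theta: float = 60.0,
                      cfg: Optional[PipelineConfig] = None) -> EdgeRegions:
    """Partition the foreground along the midline of the edge stripes.

    Steps: strict thresholding of the grayscale edges at ``theta``,
    morphological closing into edge stripes, medial-axis skeletonisation
    into a midline, 1-px dilation (against pixel gaps), then 8-connected
    labelling of the foreground minus the dilated midline.  Regions come
    back labelled 1..L in order of descending area.
    """
    cfg = cfg or PipelineConfig()
    g = _edges(G)
    f = _mask(F)
    binary = g > theta
    if cfg.edge_closing_radius > 0:
        binary = morphology.closing(
            binary, morphology.disk(cfg.edge_closing_radius))
    midline = morphology.medial_axis(binary) if binary.any() else binary
    if cfg.midline_dilation > 0:
        midline = morphology.dilation(
            midline, morphology.disk(cfg.midline_dilation))
    comp = measure.label(f & ~midline, connectivity=2)
    ncomp = int(comp.max())
    regions = np.zeros(f.shape, dtype=np.int32)
    if ncomp:
        areas = np.bincount(comp.ravel())[1:]
        order = np.argsort(areas, kind="stable")[::-1]
        for new, old in enumerate(order, start=1):
            regions[comp == old + 1] = new
    return EdgeRegions(regions=regions, L=ncomp,
                       midline=BinaryMask(midline & f, role="boundary"))


# ---------------------------------------------------------------------------
# Bodies
# ---------------------------------------------------------------------------

def correct_body_overlap(bodyA, bodyB) -> tuple[BinaryMask, BinaryMask]:
    """Split the intersection of two body masks by nearest centroid.

    Centroids are taken on the *original* masks; each contested pixel goes
    to the body with the nearer Euclidean centroid (ties to the first
    body).  The outputs are disjoint and their union equals the input
    union.
    """
    a, b = _mask(bodyA), _mask(bodyB)
    if not a.any() or not b.any():
        return BinaryMask(a, "body"), BinaryMask(b, "body")
    inter = a & b
    if inter.any():
        ca = np.array(_centroid(a))
        cb = np.array(_centroid(b))
        rows, cols = np.nonzero(inter)
        pts = np.stack([rows, cols], axis=1).astype(float)
        da = ((pts - ca) ** 2).sum(axis=1)
        db = ((pts - cb) ** 2).sum(axis=1)
        to_a = da <= db  # tie goes to the first body
        a = a.copy(); b = b.copy()
        a[rows, cols] = to_a
        b[rows, cols] = ~to_a
    return BinaryMask(a, "body"), BinaryMask(b, "body")


# ---------------------------------------------------------------------------
# Marker construction
# ---------------------------------------------------------------------------

def assign_regions(edges: EdgeRegions, bodies: Optional[BodyRegions]) -> LabelMap:
    """Build the initial watershed markers from edge and body regions.

    Each edge region is assigned to the body with the largest overlap
    ratio ``|r ∩ b| / |r|`` (left unassigned when all ratios are zero).
    With two bodies each claiming at least one region, the two marker
    groups are the unions of each body with its regions.  Degenerate body
    information (zero or one body, or a single body claiming every region)
    is ignored and the two largest edge regions seed the groups instead.
    Leftover regions merge into the nearest group by centroid distance so
    the foreground is conserved; pixels claimed by both groups become
    background; a single surviving group flags the map unseparated.
    """
    R = edges.regions
    L = edges.L
    if L < 1:
        return LabelMap(labels=np.zeros(R.shape, np.uint8), unseparated=True)

    groups: list[np.ndarray] = []
    assigned: dict[int, int] = {}
    use_bodies = bodies is not None and len(bodies.masks) == 2
    if use_bodies:
        mA, mB = correct_body_overlap(*bodies.masks)
        corrected = [mA.pixels, mB.pixels]
        for r in range(1, L + 1):
            rmask = R == r
            area = rmask.sum()
            ratios = [float((rmask & b).sum()) / area for b in corrected]
            best = int(np.argmax(ratios))
            if ratios[best] > 0:
                assigned[r] = best
        claimed = set(assigned.values())
        if len(claimed) == 2:
            for bidx in (0, 1):
                g = corrected[bidx].copy()
                for r, owner in assigned.items():
                    if owner == bidx:
                        g |= R == r
                groups.append(g)
        else:
            use_bodies = False
            assigned = {}
    if not use_bodies:
        groups = [(R == 1).copy()]
        if L >= 2:
            groups.append((R == 2).copy())
        assigned = {1: 0}
        if L >= 2:
            assigned[2] = 1

    # merge any leftover regions into the nearest group (by centroid)
    if groups:
        g_cent = [np.array(_centroid(g)) for g in groups]
        for r in range(1, L + 1):
            if r in assigned:
                continue
            rmask = R == r
            if not use_bodies and r <= 2:
                continue
            c = np.array(_centroid(rmask))
            nearest = int(np.argmin([((c - gc) ** 2).sum() for gc in g_cent]))
            groups[nearest] = groups[nearest] | rmask

    labels = np.zeros(R.shape, dtype=np.uint8)
    if len(groups) == 1:
        labels[groups[0]] = 1
        return LabelMap(labels=labels, unseparated=True)
    areas = [int(g.sum()) for g in groups]
    big, small = (0, 1) if areas[0] >= areas[1] else (1, 0)
    conflict = groups[0] & groups[1]
    labels[groups[big]] = 1
    labels[groups[small]] = 2
    labels[conflict] = 0  # contested pixels fall back to background
    present = set(np.unique(labels)) - {0}
    return LabelMap(labels=labels, unseparated=len(present) < 2)


# ---------------------------------------------------------------------------
# Watershed fill
# ---------------------------------------------------------------------------

def watershed_fill(markers: LabelMap, F, G) -> LabelMap:
    """Marker-controlled watershed over the edge-intensity landscape.

    High edge intensity acts as a ridge; flooding is restricted to the
    foreground and marker pixels keep their labels verbatim.  Foreground
    components unreachable from any marker are assigned the label of the
    nearest labelled pixel so the labels exactly tile the foreground.
    """
    f = _mask(F)
    seeds = np.where(f, markers.labels.astype(np.int32), 0)
    if not seeds.any():
        return LabelMap(labels=np.zeros(f.shape, np.uint8), unseparated=True)
    elevation = _edges(G)
    out = sk_seg.watershed(elevation, markers=seeds, mask=f, connectivity=2)
    leftover = f & (out == 0)
    if leftover.any():
        dist, (ir, ic) = ndimage.distance_transform_edt(
            out == 0, return_indices=True)
        out = np.where(leftover, out[ir, ic], out)
    out = np.where(f, out, 0).astype(np.uint8)
    present = set(np.unique(out)) - {0}
    return LabelMap(labels=out, unseparated=len(present) < 2)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def segment_frame(
    frame,
    F,
    E,
    bodies: Optional[BodyRegions] = None,
    cfg: Optional[PipelineConfig] = None,
    completer: Optional[Callable] = None,
) -> LabelMap:
    """Segment one frame into two instances (or flag it unseparated).

    Tails are removed from the foreground by binary opening.  If the
    remaining foreground has two or more connected components the
    instances are disjoint and component labelling suffices.  Otherwise
    the frame is occluding: the edge image is run through edge completion
    (``completer``; defaults to the minimal-cost-path fallback), the
    midline partitions the foreground into edge regions, body regions
    refine the markers, and the watershed fills the foreground.  If the
    result still holds a single label, the whole foreground is flagged
    unseparated.
    """
    cfg = cfg or PipelineConfig()
    f = remove_tails(_mask(F), cfg.tail_opening_radius).pixels
    if not f.any():
        return LabelMap(labels=np.zeros(f.shape, np.uint8), unseparated=True)
    lab, occluding = label_instances(f)
    if not occluding:
        return lab
    # occluding: complete the edges, partition, combine with bodies
    if completer is None:
        completed = complete_edges_fallback(E, f, cfg.theta)
    else:
        completed = completer(E, f, cfg.theta)
    edges = find_edge_regions(completed, f, cfg.theta, cfg)
    if edges.L < 1:
        out = np.where(f, 1, 0).astype(np.uint8)
        return LabelMap(labels=out, unseparated=True)
    markers = assign_regions(edges, bodies)
    markers = LabelMap(labels=np.where(f, markers.labels, 0), unseparated=markers.unseparated)
    result = watershed_fill(markers, f, _edges(completed))
    if len(result.present_labels()) < 2:
        out = np.where(f, 1, 0).astype(np.uint8)
        return LabelMap(labels=out, unseparated=True)
    return result
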