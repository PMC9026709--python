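"""Synthetic data: arena simulator, occlusion augmentation, edge degradation.

Three generators live here.

* :func:`simulate_sequence` renders a fixed-camera arena with two bright,
  textured, smoothly deforming capsule-shaped instances on a darker static
  background, with a controlled fraction of occluding frames and exact
  per-frame ground-truth label maps.  It is the package's source of study
  conditions: every end-to-end test and the acceptance run draw their input
  from it.
* :func:`augment_pair` builds the copy-paste occlusion dataset: two
  single-instance crops from non-occluding frames are rotated, translated
  and composited (one instance rendered over the other) into 256x256
  samples with automatically generated ground-truth edges and the
  separating-edge mask.
* :func:`degrade_edges` turns a perfect ground-truth edge image into an
  "unseparated" one by deleting arcs of the separating edge and softening
  the survivors — a parametric stand-in for learned edge-degradation
  models, chosen for its determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.restoration import inpaint_biharmonic

from .core_io import BinaryMask, EdgeImage, Frame, LabelMap, PipelineConfig, RunLog

__all__ = [
    "SimScene",
    "AugmentedSample",
    "simulate_sequence",
    "synthetic_bodies",
    "augment_pair",
    "compute_separating_boundary",
    "inpaint_blur",
    "render_aGT",
    "degrade_edges",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Scene description and rendering
# ---------------------------------------------------------------------------

@dataclass
class SimScene:
    """Two deformable capsule instances in a fixed-camera arena.

    Each instance is a bent capsule: a quadratic centerline of half-length
    ``half_length`` swept with a tapered half-width profile peaking at
    ``half_width``.  Instances are bright (around ``instance_level``) with
    a per-instance moving texture; the static background is darker
    (``background_level``).  ``occlusion_fraction`` of the frames are
    scheduled as occluding: the designated upper instance is rendered over
    the other and the two masks genuinely overlap.
    """

    height: int = 176
    width: int = 176
    background_level: float = 40.0
    background_texture_amp: float = 6.0
    instance_level: float = 190.0
    instance_texture_amp: float = 30.0
    seam_shadow: float = 0.35
    noise_sigma: float = 2.5
    half_length: tuple[float, float] = (26.0, 25.0)
    half_width: tuple[float, float] = (10.0, 9.5)
    occlusion_fraction: float = 0.15
    mean_episode_len: int = 12
    max_speed: float = 2.5
    seed: int = 0

    def radius(self, i: int) -> float:
        """Upper bound on the instance's radial extent from its center."""
        return self.half_length[i] + self.half_width[i] + 3.0

    def validate(self) -> None:
        if not 0.0 <= self.occlusion_fraction <= 0.7:
            raise ValueError("occlusion_fraction must lie in [0, 0.7]")
        big = 2 * (max(self.radius(0), self.radius(1)) + 6)
        if big >= min(self.height, self.width):
            raise ValueError("instances too large for arena")
        apart = self.radius(0) + self.radius(1) + 16
        if apart + 12 >= min(self.height, self.width):
            raise ValueError("instances too large for arena")


def _rot(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


def _capsule_mask(shape, center, phi, bend, L, w0):
    """Boolean mask of a bent capsule; rendered only inside its bbox."""
    H, W = shape
    s = np.linspace(-1.0, 1.0, int(2 * L) + 1)
    xs = s * L
    ys = bend * L * (s ** 2 - 1.0 / 3.0)
    pts = (_rot(phi) @ np.stack([xs, ys])).T + np.asarray(center)  # (S, 2) row,col
    widths = w0 * (0.55 + 0.45 * np.sqrt(np.clip(1 - s ** 2, 0, 1)))
    rad = L + w0 + abs(bend) * L + 2
    r0 = max(0, int(center[0] - rad)); r1 = min(H, int(center[0] + rad) + 1)
    c0 = max(0, int(center[1] - rad)); c1 = min(W, int(center[1] + rad) + 1)
    mask = np.zeros((H, W), dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rr, cc = np.mgrid[r0:r1, c0:c1]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)  # (N, 2)
    d2 = ((grid[None, :, :] - pts[:, None, :]) ** 2).sum(axis=2)  # (S, N)
    inside = (d2 <= (widths ** 2)[:, None]).any(axis=0)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


def _instance_intensity(shape, mask, center, phi, tex_tile, level, amp):
    """Texture that translates and rotates rigidly with the body."""
    H, W = shape
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.zeros(0)
    d = np.stack([rows - center[0], cols - center[1]]).astype(float)
    local = _rot(-phi) @ d
    T = tex_tile.shape[0]
    coords = np.stack([local[0] * 1.5 + T / 2, local[1] * 1.5 + T / 2])
    tex = ndimage.map_coordinates(tex_tile, coords, order=1, mode="wrap")
    return level + amp * tex


def _smooth_noise(rng, size, sigma):
    t = rng.standard_normal((size, size))
    t = ndimage.gaussian_filter(t, sigma, mode="wrap")
    t /= max(np.abs(t).max(), 1e-9)
    return t


def _schedule_occlusion(rng, T, frac, mean_len):
    occ = np.zeros(T, dtype=bool)
    n_occ = int(round(frac * T))
    if n_occ == 0:
        return occ
    k = max(1, int(round(n_occ / mean_len)))
    lengths = [n_occ // k + (1 if i < n_occ % k else 0) for i in range(k)]
    block = T // k
    for i, ln in enumerate(lengths):
        lo = i * block + (3 if i == 0 else 1)
        hi = min((i + 1) * block, T) - ln - 1
        start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(lo, 1)
        start = min(start, T - ln)
        occ[start:start + ln] = True
    return occ


def simulate_sequence(
    scene: SimScene, T: int
) -> tuple[list[Frame], list[LabelMap], np.ndarray]:
    """Render ``T`` frames with exact ground truth.

    Returns ``(frames, gt_maps, upper)``: ground-truth label maps hold the
    visible silhouettes (label 1 and 2 are stable instance identities; the
    occluded parts of the lower instance are not labelled), and ``upper[t]``
    is the instance id rendered on top in frame ``t`` (0 when the frame is
    non-occluding).  Deterministic given ``scene.seed``; the realised
    occluding-frame fraction equals the schedule by construction.
    """
    if T < 1:
        raise ValueError("need T >= 1")
    scene.validate()
    H, W = scene.height, scene.width
    rng = np.random.default_rng(np.random.SeedSequence(scene.seed))
    bg_tex = _smooth_noise(rng, max(H, W), 6.0)
    bg = np.clip(
        scene.background_level + scene.background_texture_amp * bg_tex[:H, :W], 0, 255
    )
    bg_rgb = np.repeat(np.rint(bg)[:, :, None], 3, axis=2).astype(np.uint8)
    tex = [_smooth_noise(rng, 96, 2.0), _smooth_noise(rng, 96, 2.0)]

    occ = _schedule_occlusion(rng, T, scene.occlusion_fraction, scene.mean_episode_len)
    # per-episode choice of which instance is on top
    upper = np.zeros(T, dtype=int)
    t = 0
    while t < T:
        if occ[t]:
            end = t
            while end < T and occ[end]:
                end += 1
            upper[t:end] = int(rng.integers(1, 3))
            t = end
        else:
            t += 1

    R = [scene.radius(0), scene.radius(1)]
    margin = 6.0
    lo1 = np.array([R[0] + margin] * 2)
    hi1 = np.array([H - R[0] - margin, W - R[0] - margin])
    lo2 = np.array([R[1] + margin] * 2)
    hi2 = np.array([H - R[1] - margin, W - R[1] - margin])
    d_occ = 0.45 * (R[0] + R[1])
    d_free = R[0] + R[1] + 12.0

    c1 = np.array([H * 0.5, W * 0.38])
    psi0 = rng.uniform(0, 2 * np.pi)
    c2 = np.clip(c1 + d_free * np.array([math.cos(psi0), math.sin(psi0)]), lo2, hi2)
    v1 = np.zeros(2)
    v2 = np.zeros(2)
    phi = np.array([rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)])
    bend = np.array([0.0, 0.0])

    frames: list[Frame] = []
    gts: list[LabelMap] = []

    def _render2(center):
        return _capsule_mask((H, W), center, phi[1], bend[1], *_dims(scene, 1))

    for t in range(T):
        # smooth motion of instance 1
        v1 = 0.85 * v1 + 0.6 * rng.standard_normal(2)
        speed = np.linalg.norm(v1)
        if speed > scene.max_speed:
            v1 *= scene.max_speed / speed
        c1 = np.clip(c1 + v1, lo1, hi1)
        phi += rng.normal(0, 0.06, size=2)
        bend = np.clip(bend + rng.normal(0, 0.03, size=2), -0.35, 0.35)

        # instance 2: its own smooth walk with a spring toward the
        # scheduled separation distance
        target = d_occ if occ[t] else d_free
        dvec = c2 - c1
        d = max(float(np.linalg.norm(dvec)), 1e-6)
        u_away = dvec / d
        v2 = 0.8 * v2 + 0.5 * rng.standard_normal(2) + 0.3 * (target - d) * u_away
        speed = np.linalg.norm(v2)
        if speed > 1.6 * scene.max_speed:
            v2 *= 1.6 * scene.max_speed / speed
        c2 = np.clip(c2 + v2, lo2, hi2)

        m1 = _capsule_mask((H, W), c1, phi[0], bend[0], *_dims(scene, 0))
        m2 = _render2(c2)
        # enforce the scheduled overlap status exactly; walls may block
        # instance 2, in which case instance 1 yields instead
        for _ in range(60):
            overlap = (m1 & m2).any()
            touching = overlap or (morphology.dilation(m1, _SQUARE3) & m2).any()
            if occ[t]:
                covered = not (m2 & ~m1).any() or not (m1 & ~m2).any()
                if overlap and not covered:
                    break
                step = -2.5 if not overlap else 2.5
            else:
                if not touching:
                    break
                step = 2.5
            dvec = c2 - c1
            d = max(float(np.linalg.norm(dvec)), 1e-6)
            u = dvec / d
            cand = np.clip(c2 + step * u, lo2, hi2)
            if np.linalg.norm(cand - c2) < 0.5 * abs(step):
                c1 = np.clip(c1 - step * u, lo1, hi1)
                m1 = _capsule_mask((H, W), c1, phi[0], bend[0], *_dims(scene, 0))
            c2 = cand
            m2 = _render2(c2)

        img = bg.copy()
        order = [0, 1] if upper[t] != 1 else [1, 0]
        masks = [m1, m2]
        centers = [c1, c2]
        for i in order:  # lower painted first, upper overwrites
            vals = _instance_intensity(
                (H, W), masks[i], centers[i], phi[i], tex[i],
                scene.instance_level, scene.instance_texture_amp,
            )
            img[masks[i]] = vals
        if occ[t] and scene.seam_shadow > 0:
            # the upper animal casts a soft shadow along the separating edge
            up_mask = masks[upper[t] - 1]
            low_mask = masks[2 - upper[t]]
            seam = compute_separating_boundary(up_mask, low_mask).pixels
            if seam.any():
                soft = ndimage.gaussian_filter(seam.astype(float), 0.8)
                soft /= max(soft.max(), 1e-9)
                img = img * (1.0 - scene.seam_shadow * soft)
        if scene.noise_sigma > 0:
            img = img + rng.normal(0, scene.noise_sigma, size=img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        frames.append(Frame(pixels=np.repeat(img[:, :, None], 3, axis=2), index=t))

        labels = np.zeros((H, W), dtype=np.uint8)
        if occ[t]:
            up = upper[t] - 1
            low_i = 1 - up
            labels[masks[low_i]] = low_i + 1
            labels[masks[up]] = up + 1
        else:
            labels[m1] = 1
            labels[m2] = 2
        gts.append(LabelMap(labels=labels, unseparated=False))
    return frames, gts, upper


def _dims(scene: SimScene, i: int) -> tuple[float, float]:
    return scene.half_length[i], scene.half_width[i]


def synthetic_bodies(
    gt: LabelMap, erosion_radius: int = 3, dilation_radius: int = 0
) -> list[np.ndarray]:
    """Body-region masks derived from a ground-truth label map.

    Emulates a body-part detector: each instance's visible silhouette is
    eroded (dropping the narrow head/tail-like extremities) and optionally
    re-dilated, which lets neighbouring bodies overlap the way a real
    region detector's outputs do.  Returns a list of boolean masks.
    """
    out = []
    for lab in (1, 2):
        m = gt.labels == lab
        if erosion_radius > 0:
            m = morphology.erosion(m, morphology.disk(erosion_radius))
        if dilation_radius > 0:
            m = morphology.dilation(m, morphology.disk(dilation_radius))
        if m.any():
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# Separating boundary, ground-truth edges
# ---------------------------------------------------------------------------

def _as_bool(m) -> np.ndarray:
    return m.pixels if isinstance(m, BinaryMask) else np.asarray(m, bool)


def compute_separating_boundary(upper, lower) -> BinaryMask:
    """1-px separating edge: the upper instance's inner contour strictly
    inside the union of the two masks.

    The contour is the 8-connected 1-px inner boundary of the upper mask;
    pixels on the 1-px external boundary of ``upper | lower`` are excluded.
    Empty when the masks are disjoint.
    """
    u, l = _as_bool(upper), _as_bool(lower)
    if u.shape != l.shape:
        raise ValueError("mask shapes differ")
    union = u | l
    contour_u = u & ~ndimage.binary_erosion(u, structure=_SQUARE3)
    interior = ndimage.binary_erosion(union, structure=_SQUARE3)
    return BinaryMask(pixels=contour_u & interior, role="separating")


def render_aGT(upper, lower, thickness: int = 1) -> EdgeImage:
    """Ground-truth edge image of the composited pair.

    Nonzero (255) exactly on the contours of the visible silhouettes: the
    external contour of the union plus the separating edge, dilated to the
    requested thickness (1 or 2 px).
    """
    if thickness not in (1, 2):
        raise ValueError("thickness must be 1 or 2")
    u, l = _as_bool(upper), _as_bool(lower)
    union = u | l
    ext = union & ~ndimage.binary_erosion(union, structure=_SQUARE3)
    edges = ext | compute_separating_boundary(u, l).pixels
    if thickness == 2:
        edges = morphology.dilation(edges, np.ones((2, 2), dtype=bool))
    return EdgeImage(intensities=edges.astype(np.float64) * 255.0,
                     provenance="ground-truth")


# ---------------------------------------------------------------------------
# Inpaint blur
# ---------------------------------------------------------------------------

def inpaint_blur(aRGB, S_core, radius: int = 7, aux_background=None) -> np.ndarray:
    """Remove the unrealistic seam along the separating edge with an
    inpaint-based blur.

    The zeroed background is temporarily replaced by the auxiliary texture
    so the blur near the external boundary is not biased toward black, the
    separating-edge pixels are inpainted (biharmonic interpolation from
    their surroundings), a radius-limited blur is blended over the seam
    neighbourhood, and the background zeros are restored.  Pixels farther
    than ``radius`` (Chebyshev) from ``S_core`` are returned unchanged.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = aRGB.pixels if isinstance(aRGB, Frame) else np.asarray(aRGB)
    img = img.astype(np.float64)
    S = _as_bool(S_core)
    if not S.any():
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)
    bg = (img == 0).all(axis=2)
    work = img.copy()
    if aux_background is not None:
        aux = np.asarray(aux_background, dtype=np.float64)
        if aux.ndim == 2:
            aux = np.repeat(aux[:, :, None], 3, axis=2)
        if aux.shape[:2] != img.shape[:2]:
            raise ValueError("auxiliary background must cover the image")
        work[bg] = aux[bg]
    filled = inpaint_biharmonic(work / 255.0, S, channel_axis=-1) * 255.0
    # Chebyshev distance from the seam limits where the blur may act
    dist = ndimage.distance_transform_cdt(~S, metric="chessboard")
    band = dist <= radius
    blurred = ndimage.gaussian_filter(filled, sigma=(radius / 3.0, radius / 3.0, 0))
    weight = np.clip(1.0 - dist / (radius + 1.0), 0.0, 1.0)[:, :, None]
    out = np.where(band[:, :, None], (1 - weight) * filled + weight * blurred, filled)
    out[bg] = img[bg]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentedSample:
    """One composited occlusion-training sample."""

    aRGB: np.ndarray  # crop x crop x 3 uint8
    aGT: EdgeImage
    upper_mask: BinaryMask
    lower_mask: BinaryMask
    S: BinaryMask  # separating edge dilated to aGT thickness
    angle_deg: float
    translation: tuple[float, float]
    source: tuple[int, int] = (-1, -1)


def _patch(rgb, mask):
    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    return rgb[r0:r1, c0:c1].copy(), mask[r0:r1, c0:c1].copy()


def _rotate_patch(rgb, mask, angle_deg):
    if angle_deg % 360 == 0:
        return rgb, mask
    r = ndimage.rotate(rgb, angle_deg, reshape=True, order=1, mode="constant")
    m = ndimage.rotate(mask.astype(np.uint8), angle_deg, reshape=True, order=0,
                       mode="constant").astype(bool)
    return np.clip(np.rint(r), 0, 255).astype(np.uint8), m


def _paste(canvas_rgb, canvas_mask, rgb, mask, center_rc):
    """Paste a patch so its bbox center lands at ``center_rc``; clips at edges."""
    h, w = mask.shape
    r0 = int(round(center_rc[0] - h / 2))
    c0 = int(round(center_rc[1] - w / 2))
    H, W = canvas_mask.shape
    rs, cs = max(0, r0), max(0, c0)
    re, ce = min(H, r0 + h), min(W, c0 + w)
    if rs >= re or cs >= ce:
        return
    pr, pc = rs - r0, cs - c0
    sub = mask[pr:pr + (re - rs), pc:pc + (ce - cs)]
    canvas_mask[rs:re, cs:ce] |= sub
    canvas_rgb[rs:re, cs:ce][sub] = rgb[pr:pr + (re - rs), pc:pc + (ce - cs)][sub]


def augment_pair(
    instA: tuple[np.ndarray, np.ndarray],
    instB: tuple[np.ndarray, np.ndarray],
    cfg: Optional[PipelineConfig] = None,
    aux_background: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    log: Optional[RunLog] = None,
    source: tuple[int, int] = (-1, -1),
) -> list[AugmentedSample]:
    """Composite two masked single-instance crops into occlusion samples.

    For the pair: ``rotation_count`` base rotations evenly spaced over 360
    degrees with a seeded jitter, each placed at its base position plus
    ``translation_count`` translated copies (direction uniform, magnitude
    0.25-0.75 of the mean instance diameter).  Instance B is always the
    upper instance.  A fraction of base placements intentionally keeps the
    instances disjoint.  Returns ``rotation_count * (1 + translation_count)``
    samples per pair, minus any logged skips.
    """
    cfg = cfg or PipelineConfig()
    rng = rng or cfg.rng("augment")
    log = log or RunLog()
    crop = cfg.crop_size
    rgbA, maskA = instA
    rgbB, maskB = instB
    pA = _patch(np.asarray(rgbA), np.asarray(maskA, bool))
    pB = _patch(np.asarray(rgbB), np.asarray(maskB, bool))
    diam = [2 * math.sqrt(p[1].sum() / math.pi) for p in (pA, pB)]
    mean_diam = float(np.mean(diam))
    if aux_background is None:
        # tile the upper instance's own texture across the crop
        reps = (crop // pB[0].shape[0] + 1, crop // pB[0].shape[1] + 1, 1)
        aux_background = np.tile(pB[0], reps)[:crop, :crop]

    samples: list[AugmentedSample] = []
    n_rot = cfg.rotation_count
    center = np.array([crop / 2.0, crop / 2.0])
    for k in range(n_rot):
        angle = k * 360.0 / n_rot + rng.uniform(-cfg.rotation_jitter_deg,
                                                cfg.rotation_jitter_deg)
        rB, mB = _rotate_patch(*pB, angle)
        for j in range(1 + cfg.translation_count):
            for attempt in range(10):
                disjoint = rng.uniform() < cfg.disjoint_fraction
                theta = rng.uniform(0, 2 * np.pi)
                if disjoint:
                    mag = rng.uniform(1.05, 1.3) * mean_diam * (1 + 0.2 * attempt)
                else:
                    mag = rng.uniform(0.2, 0.5) * mean_diam
                offset = np.array([math.sin(theta), math.cos(theta)]) * mag
                trans = (0.0, 0.0)
                if j > 0:
                    tdir = rng.uniform(0, 2 * np.pi)
                    tmag = rng.uniform(0.25, 0.75) * mean_diam
                    trans = (tmag * math.sin(tdir), tmag * math.cos(tdir))
                    offset = offset + np.array(trans)
                cA = center - offset / 2
                cB = center + offset / 2
                canvas = np.zeros((crop, crop, 3), dtype=np.uint8)
                lower = np.zeros((crop, crop), dtype=bool)
                upper = np.zeros((crop, crop), dtype=bool)
                _paste(canvas, lower, *pA, cA)
                _paste(canvas, upper, rB, mB, cB)  # B over A: B is the upper
                placed = upper.any() and lower.any()
                touching = (morphology.dilation(upper, _SQUARE3) & lower).any()
                if placed and not (disjoint and touching):
                    break
            else:
                log.log("augment_skip", angle=angle, placement=j, source=source)
                continue
            S_core = compute_separating_boundary(upper, lower)
            aGT = render_aGT(upper, lower, thickness=cfg.aGT_thickness)
            aRGB = inpaint_blur(canvas, S_core, cfg.inpaint_radius, aux_background)
            S = S_core.pixels
            if cfg.aGT_thickness == 2:
                S = morphology.dilation(S, np.ones((2, 2), dtype=bool))
            samples.append(AugmentedSample(
                aRGB=aRGB, aGT=aGT,
                upper_mask=BinaryMask(upper, "upper-instance"),
                lower_mask=BinaryMask(lower, "body"),
                S=BinaryMask(S, "separating"),
                angle_deg=float(angle), translation=trans, source=source,
            ))
    return samples


# ---------------------------------------------------------------------------
# Parametric edge degradation
# ---------------------------------------------------------------------------

def _order_curve(coords: np.ndarray) -> np.ndarray:
    """Order curve pixels into a chain by nearest-neighbour walking."""
    n = len(coords)
    if n <= 2:
        return np.arange(n)
    # prefer an endpoint (pixel with a single 8-neighbour) as the start
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    adj = (d2 > 0) & (d2 <= 2)
    deg = adj.sum(axis=1)
    start = int(np.argmin(deg + (deg == 0)))
    order = [start]
    used = np.zeros(n, dtype=bool)
    used[start] = True
    cur = start
    for _ in range(n - 1):
        dist = d2[cur].copy().astype(float)
        dist[used] = np.inf
        nxt = int(np.argmin(dist))
        if not np.isfinite(dist[nxt]):
            break
        order.append(nxt)
        used[nxt] = True
        cur = nxt
    # append any leftovers (disconnected fragments) in scan order
    order.extend(np.nonzero(~used)[0].tolist())
    return np.asarray(order)


def degrade_edges(
    aGT: EdgeImage,
    S_core,
    *,
    removal_fraction: Optional[float] = None,
    removal_range: tuple[float, float] = (0.3, 0.7),
    max_arcs: int = 3,
    blur_sigma: float = 1.0,
    attenuation: float = 0.7,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
    thickness: int = 1,
) -> EdgeImage:
    """Break the separating edge the way an imperfect detector would.

    Removes 1 to ``max_arcs`` contiguous arcs totalling a seeded fraction of
    the separating-edge pixels, then blurs and attenuates the surviving
    separating-edge pixels.  The external contour is untouched; the result
    is an "unseparated" edge image whose upper contour is no longer closed.
    """
    rng = rng or np.random.default_rng(seed)
    E = aGT.intensities if isinstance(aGT, EdgeImage) else np.asarray(aGT, float)
    out = E.copy()
    S = _as_bool(S_core)
    if not S.any():
        raise ValueError("S_core must be nonempty")
    S_reg = S
    if thickness == 2:
        S_reg = morphology.dilation(S, np.ones((2, 2), dtype=bool))
    S_reg = S_reg & (E > 0)

    frac = removal_fraction
    if frac is None:
        frac = float(rng.uniform(*removal_range))
    coords = np.argwhere(S)
    order = _order_curve(coords)
    chain = coords[order]
    n = len(chain)
    n_remove = int(round(frac * n))
    removed = np.zeros(E.shape, dtype=bool)
    if n_remove > 0:
        k = int(rng.integers(1, max_arcs + 1)) if n_remove < n else 1
        splits = np.sort(rng.integers(0, n_remove + 1, size=k - 1)) if k > 1 else []
        lengths = np.diff(np.concatenate([[0], splits, [n_remove]])).astype(int)
        for ln in lengths:
            if ln <= 0:
                continue
            start = int(rng.integers(0, max(n - ln, 0) + 1))
            arc = chain[start:start + ln]
            removed[arc[:, 0], arc[:, 1]] = True
        if thickness == 2:
            removed = morphology.dilation(removed, np.ones((2, 2), dtype=bool))
        out[removed & S_reg] = 0.0
    survivors = S_reg & ~removed
    if survivors.any() and (blur_sigma > 0 or attenuation != 1.0):
        blurred = ndimage.gaussian_filter(out, blur_sigma) if blur_sigma > 0 else out
        out[survivors] = np.clip(attenuation * blurred[survivors], 0, 255)
    return EdgeImage(intensities=np.clip(out, 0, 255), provenance="detector")
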