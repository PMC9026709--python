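# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `sepatrack`. It documents what the code computes; every
number quoted here is produced by the test suite or the acceptance
script, not asserted from elsewhere.

## Setting and assumptions

The pipeline assumes a fixed camera, a static background, and **exactly
two** similar instances that can touch and occlude each other but never
leave the scene or hide. Under these constraints the number of instances
is known a priori and identity re-entry never has to be solved; the whole
difficulty is keeping the two identities apart through contact episodes.
Tails are deliberately ignored throughout (binary opening removes them
from the foreground): their thin, fast-changing shapes carry no
information about body identity and only add noise.

## Pre-processing

The background is the per-pixel, per-channel temporal **mode** of up to
2000 uniformly sampled frames, on integer intensity bins. Ties resolve to
the lowest intensity — the mode of 8-bit data frequently ties on flat
regions and an arbitrary tie-break would make runs irreproducible.
Foreground extraction subtracts the background after a per-frame gain
normalisation (frame rescaled by the ratio of background median to frame
median). This is the package's concrete realisation of
intensity-histogram robustification against global illumination shifts
and reflections; it is deliberately simple and exactly invertible on
synthetic data. Defaults: difference threshold 30/255, speckle
opening/closing with a disk of radius 2, minimum component area 0.1 % of
the image, tail-removal opening radius 3 px. All are config fields.

The mode estimator is consistent only where the background is visible in
more than half of the sampled frames; a sequence in which an animal
dwells on one spot for most of the clip will absorb it into the
background. The acceptance suite verifies bit-exact recovery on a
noise-free 200-frame sequence at every pixel satisfying the >50 %
condition; short clips (tens of frames) do not satisfy it and degrade
visibly.

## Edge detection and completion

Edge detection is a provider interface: anything that maps a frame to a
[0, 255] intensity image can drive the pipeline; the default provider is
Canny (σ = 1.4, hysteresis 40/120). Edge images are always masked to the
dilated foreground (radius 2) so that arena clutter cannot enter the
segmentation.

For occluding frames whose separating edge is broken, the deterministic
**completion fallback** skeletonises the thresholded edges, finds
skeleton endpoints strictly inside the foreground, and joins endpoint
pairs greedily by ascending path cost, where a pixel costs
1 + (255 − E)/255 and paths may not leave the foreground or cross its
external boundary. Path costs are geometric (diagonal steps weighted by
their length) so that a straight bridge strictly beats a staircase of
equal pixel count. The cost blends path length with edge evidence: with
no evidence the bridge is the shortest admissible path, and any detected
partial edge pulls the path onto itself.

The learned completion stack is represented by its loss and data
machinery: the inpaint mask M = F∖B (boundary B = {E > θ_b}, strict
inequality; the value at equality is excluded because a threshold is a
lower bound on evidence), the two-term masked binary cross-entropy with
per-mask mean reduction and ε = 10⁻⁷ clipping (an empty mask contributes
0), the separating-edge emphasis mask S dilated by 2 px, and the
discriminator re-weighting that keeps upper-instance edge intensities and
halves all others. A full adversarial training harness is out of scope
here; the deterministic fallback is the completion path exercised by the
pipeline and the tests.

## Synthetic data

### Simulator

`simulate_sequence` renders two bent-capsule instances (quadratic
centerline, tapered width profile) with rigidly co-moving smooth texture,
on a static textured background, plus per-frame Gaussian noise. Defaults:
176×176 arena, background level 40 ± 6, instance level 190 ± 30, noise
σ = 2.5, half-lengths 26/25 px and peak half-widths 10/9.5 px — two
adult animals of near-equal size, each covering ≈4 % of the arena.
Occlusion episodes (mean length 12 frames) are scheduled to cover the
requested fraction of frames exactly; during an episode one instance (the
per-episode "upper") is rendered over the other and a soft shadow is
drawn along the separating boundary — the same physical cue that makes
the separating edge *weakly* visible in real footage, which is precisely
what the edge-completion stage exists for. Motion is a damped random walk
for instance 1 and a damped walk with a distance spring for instance 2;
scheduled overlap status is enforced exactly by nudging positions (moving
instance 1 away from walls when instance 2 is blocked). As a consequence
the realised occluding-frame fraction equals the schedule, at the price
of occasional fast entries into and exits out of contact.

What the simulator does **not** emulate: fur texture and self-shadowing,
perspective and size change, rearing (3-D pose), cage furniture,
reflections and urine artefacts, more than two animals. Passing tests on
simulator data therefore demonstrate the internal consistency of the
algorithmic chain under its stated assumptions, not performance on any
particular real recording.

### Occlusion augmentation

`augment_pair` composites two single-instance crops into 256×256 samples:
5 base rotations evenly spaced over 360° with uniform jitter in ±15°, and
for each rotation the base placement plus 2 translated copies (direction
uniform in [0, 2π), magnitude uniform in 0.25–0.75 of the mean instance
diameter) — 15 samples per input pair. Instance B is always composited on
top and is therefore the upper instance. By default 20 % of placements
intentionally keep the instances separated (with a guaranteed 1-px gap),
for training variety; both the jitter bound and the translation law are
package choices exposed in config, as is the disjoint proportion.

The separating boundary is the 1-px inner contour of the upper mask
strictly inside the union of both masks (the 1-px external union boundary
excluded). Ground-truth edge images are nonzero exactly on the external
union contour plus the separating edge, at thickness 1 or 2 px. The seam
between the composited instances is unrealistic (no shadow), so it is
removed by an **inpaint-based blur**: the background is temporarily
replaced by an auxiliary instance-texture tile (so the blur is not biased
toward black), the seam pixels are inpainted by biharmonic interpolation,
a blur is blended within the seam neighbourhood, and the zeroed
background is restored. The operation is local by construction: pixels
farther than the radius (default 7 px, Chebyshev) from the seam are
bit-identical to the input; a constant image is a fixed point.

### Parametric edge degradation

Learned edge detectors break the separating edge in characteristic ways;
`degrade_edges` is a deterministic, parametric stand-in chosen so the
completion stage has a testable input distribution: it removes 1–3
contiguous arcs totalling a seeded 30–70 % of the separating-edge pixels,
then blurs (σ = 1.0) and attenuates (×0.7) the survivors, leaving the
external contour untouched. With removal 0, blur 0 and attenuation 1 it
is the identity.

## Segmentation details

* θ = 60 on the [0, 255] scale, strict inequality. Closing radius 2 and
  midline dilation 1 px: edge stripes can be several pixels wide, and a
  1-px dilation of the medial axis closes single-pixel gaps without
  eating noticeably into the regions.
* Overlap-ratio denominator is the edge-region area; any positive overlap
  assigns. Bodies are ignored when fewer than two are present or when a
  single body claims every region — region size order alone then decides
  the two groups.
* Regions beyond the two largest merge into the nearest group by centroid
  distance instead of being dropped, so the output labels exactly tile
  the (tail-removed) foreground.
* The watershed floods the raw edge-intensity landscape restricted to the
  foreground; markers are preserved verbatim. Foreground components
  unreachable from any marker (possible with degenerate markers) are
  assigned to the nearest labelled pixel to preserve the tiling
  invariant.
* Degenerate inputs degrade to flagged outputs, never to exceptions: an
  empty foreground, an edge-free occluding frame, or a single surviving
  marker group all yield a map flagged *unseparated*.

## Tracking details

The preservation rule (both labels present, unflagged, each instance area
within 0.3–3.0 × the running median preserved-instance area) is a
deliberately permissive plausibility filter; its thresholds are config
fields. Warping always restarts from the most recent preserved frame —
successive pixel-wise warping smears masks over long spans, so the warp
is never chained across more than one preserved-to-preserved gap. The
2×2 bipartite matching is solved by comparing both permutations; ties go
to the identity permutation so that noise cannot flip identities on a
symmetric score. Frames before the first preserved frame receive
backward-warped provisional masks. Provisional outputs never anchor
identities and are marked `propagated` (or `flagged` if the per-frame
segmentation failed).

## Evaluation details

Best-assignment frame IoU takes the maximum of the mean instance IoU over
both label pairings, because per-frame predictions carry no identity.
Both-empty masks score IoU 1 (degenerate agreement). Boundary
precision/recall use dilation with the tolerance radius (default 0.8 % of
the image diagonal). Track switches are counted per permutation
transition between consecutive *scored* frames; flagged and lost-ID
frames are skipped without resetting the previous permutation, so a swap
cannot hide behind an occlusion gap — and a swap-and-back across a gap
counts twice. Lost-ID counting includes flagged frames.

## Problem sizes

The acceptance run uses a 600-frame, 176×176 sequence with a 15 %
occlusion schedule (the occluding-frame ratio of the motivating
recordings); the oracle segmentation check uses 100 occluding frames with
ground-truth edges and bodies, where the only error source is the
midline/watershed band along the separating edge. The test suite runs in
about two minutes on one CPU.

## Known limitations

* The edge-only path separates an occluding frame only when the seam is
  at least partially detectable; frames without any separating evidence
  are flagged and bridged by propagation, so segmentation *geometry* in
  those frames is provisional.
* The preservation rule is a stand-in for richer per-frame reliability
  models; with a pathological segmenter that confidently outputs wrong
  two-label maps, propagation can anchor on a bad frame.
* Background estimation needs enough frames (hundreds) of genuine
  motion; it is not suitable for short clips.
* Exactly two instances are supported end-to-end; the metrics and the
  matching generalise to n, the segmentation grouping does not.
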