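# Methods

## The problem and the model

Pixel classifiers for retinal-vessel segmentation under-segment thin vessels:
they are a small share of the pixels, so the training loss barely notices
them. `vesselfuse` counters this with three supervision channels derived from
one label — the original mask, a thick-vessel objective and a thin-vessel
objective — one small encoder–decoder per channel, and a fusion rule that
combines the three probability maps into the final binary segmentation.

## Skeletonization by guarded outline peeling

The skeleton is computed directly on the binary mask, with vessels
8-connected over a 4-connected background (the standard pairing that avoids
checkerboard paradoxes in thin structures).

Each sweep peels the current outline (vessel pixels with a background pixel
among their 8 neighbors; the image border counts as background). A pixel is
deleted only if it is neither

* an **end pixel** — exactly one 8-connected vessel neighbor — so vessel
  tips are never shortened, nor
* a **non-simple pixel** — deletion would change the number of foreground
  components, background components or holes in its 3×3 neighborhood. The
  test is a precomputed 256-entry lookup table: a pixel is simple iff its
  neighborhood holds exactly one 8-connected foreground component and
  exactly one 4-connected background component touching a 4-neighbor.

Two ordering choices matter and were settled empirically on shapes with
known skeletons:

* Deletions are **ordered by the Euclidean distance transform** (boundary
  first), so the surviving ridge is the medial one. Unordered peeling is
  also topology-safe but lets the centerline drift toward the last-processed
  side.
* Within a distance level, peeling runs in **four directional subpasses**
  (north-, south-, east-, west-border pixels). A single raster scan deletes
  a pixel's earlier-scanned neighbors first, then freezes the pixel as a
  spurious "end pixel", leaving one-pixel spurs on trailing corners.

Sweeps repeat until nothing changes; running the operation on its own output
therefore changes nothing (idempotence is a fixed-point property, not a
separate mechanism). Segments at most 2 px wide survive intact because every
deletion there would break the guards.

## Caliber (width) estimation and thick/thin separation

Each skeleton pixel gets width `2 × min Euclidean distance to the outline`;
every other vessel pixel inherits the width of its nearest skeleton pixel,
with exact-distance ties resolved to the smallest row-major index for
determinism. Off-vessel pixels are 0, and an isolated vessel pixel (its own
skeleton and outline) gets width 0.

Thresholding the width at **2.2 px** (inclusive on the thick side)
partitions the mask exactly: `thick ∪ thin = mask`, `thick ∩ thin = ∅`. The
training objectives are `thick ∪ skeleton` and `thin ∪ skeleton`; the
skeleton is added back so each objective keeps the complete vascular
topology.

Known behavior at ends and blobs: a finite tube's caliber genuinely falls
toward its end caps (the skeleton approaches the end-wall outline), so a
constant-width-4 tube has a few sub-threshold pixels at its ends; a width-6
tube does not. On blob-like regions (e.g. a filled disk) endpoint
preservation can leave one medial branch touching the boundary, giving a
small number of low-width pixels there. Vessel-like (tubular) geometry, the
intended domain, is unaffected; the width-recovery tests quantify this
(≥ 90 % of interior skeleton pixels within ±1.5 px of the true caliber for
tubes of width 3–11).

## Networks and losses

The per-channel classifier is a miniature U-net implemented on NumPy with
hand-derived gradients (im2col convolutions, 2×2 max-pooling, nearest
upsampling, channel-concatenation skips, Adam): `depth` encoder stages of
two 3×3 conv + ReLU layers, a bottleneck, a symmetric decoder, and a 1×1
head — sigmoid for the binary losses, 2-way softmax for the categorical
ones. Gradient correctness is pinned by numeric-differentiation tests for
all four losses. Training samples square patches whose centers lie in the
FOV, from a single seeded generator; on one CPU the whole pipeline is
bitwise-reproducible.

Losses (predictions clipped to `[1e-7, 1 - 1e-7]` before logs; mean over
pixels):

| kind | positive pixel | negative pixel |
|---|---|---|
| binary CE | −log p | −log(1−p) |
| categorical CE | −log p | −log(1−p) (2-class one-hot) |
| binary focal | −α(1−p)^γ log p | −(1−α) p^γ log(1−p) |
| categorical focal | −α₁(1−p)^γ log p | −α₀ p^γ log(1−p) |

Defaults follow the best settings for this method: categorical focal with
γ = 2.0 and per-class α = (0.75, 0.25) (0.25 on vessels); the binary focal
default is α = 0.3, γ = 3.0. With γ = 0 the focal forms reduce to α-weighted
cross-entropies; the tests check those limits to 1e−9.

Optimizer settings (Adam, lr 1e−3, batch 32, 30 epochs, 200 patches per
channel) are not part of the method's claims; they are the desk-scale
defaults used by the tests and the acceptance study.

## Fusion

Given the triplet `(p_orig, p_thick, p_thin)` and FOV mask, with
k ≥ 1 and threshold t (defaults 1.25, 0.5, comparisons inclusive):

* **weighted-any** (default): vessel iff `min(k·p_orig, 1) ≥ t` or
  `p_thick ≥ t` or `p_thin ≥ t`. Multiplying the original channel by k is
  equivalent to giving it the laxer threshold t/k = 0.4 while the
  specialized channels face the raw t. The opposite reading — raising the
  thick/thin thresholds to `min(k·t, 1)` — is available as
  `FusionConfig(strict_mode=True)`; both express "trust the original channel
  more", and the multiplicative form is the default. This reconstruction of
  the fusion step is the normative one for this package.
* **majority**: at least 2 of 3 probabilities ≥ t.
* **mean**: the average of the three ≥ t.

All three are monotone in each input, and weighted-any with k = 1 and zero
thick/thin maps reduces exactly to single-map thresholding — both properties
are tested exhaustively against independently coded pixel rules.

## Evaluation

All metrics count FOV-interior pixels only (the black exterior would inflate
specificity). AUC is the Mann–Whitney rank statistic — the probability that
a random vessel pixel outranks a random background pixel, ties ½ — which is
exact under ties and oracle-checkable, rather than a binned-ROC trapezoid.

The thin-vessel protocol separates truth vessels at a 3 px caliber boundary
and scores predictions over: the thin truth vessels dilated by 1 px, plus
FOV background pixels within 2 px of them. The exact construction of this
region is under-specified in the field; the one above is fixed here so
results are comparable run to run. F1 dispersion is the per-image mean and
sample (n−1) standard deviation.

## Synthetic data

The generator emulates what makes fundus photographs hard: branching
tubular trees with root calibers 4–9 px tapering (1 px per branch level by
default) to 1 px capillaries, drawn by stamping Euclidean disks along
random-walk centerlines inside a circular FOV; vessel density 15–25 % of the
FOV; low vessel/background contrast (0.25 in the green channel) over a
smooth radial background; a central bright stripe along vessels wider than
4 px (the light reflex); Gaussian noise (σ = 0.03). Ground-truth caliber at
a pixel is the maximum over covering strokes (thick wins at crossings), and
capillary centerline pixels are always stamped so twigs stay 8-connected.
Widths are stamped as disks because the separation algorithm's width
definition is Euclidean.

What it does **not** model: lesions and pathology, uneven illumination
fields, inter-image color variation, annotation noise, and real optic-disc
structure. Consequently the desk-scale fused F1 (roughly 0.85–0.92 across
seeds) shows that the pipeline's stages compose correctly and that fusion
helps where it should — near thin vessels, where it recovers on the order
of 0.1 additional sensitivity over single-channel thresholding — not that
the method reaches any particular accuracy on clinical benchmarks;
benchmark-scale training is out of scope here.

## Numerical and design choices

* Patch extraction zero-pads bottom/right (background semantics), enumerates
  patches row-major, and reassembly averages overlaps uniformly —
  order-independent and deterministic.
* Mask loading binarizes at half full scale, robust to anti-aliased masks.
* Preprocessing order is normalize → CLAHE → gamma. Normalization is a
  per-image z-score over FOV-interior pixels rescaled to [0, 1] (the
  exterior would dominate otherwise); a constant image returns flat 0.5 with
  a warning. CLAHE runs on the 8-bit quantization via scikit-image
  (`clahe_clip_limit` uses that library's (0, 1] clip semantics, default
  0.02, `clahe_tile` = 8 tiles per side); gamma is `x^(1/γ)`, default
  γ = 1.2. None of the method's claims depend on these defaults.
* Patch size/stride default to (48, 24) in `RunConfig` for whole-image
  work; the training harness default patch is 32 so a depth-2 network
  divides it evenly.
* Zero-denominator metrics report 0 with a warning; an all-zero confusion
  table is an error.
* Seeds: one integer seed per entry point; everything downstream (tree
  growth, noise, patch sampling, weight init, shuffling) derives from it.

## Limitations

* The NumPy networks are desk-scale by design (seconds to minutes on one
  CPU); training at clinical resolution needs a GPU framework behind the
  same interfaces.
* Skeleton centering is accurate to about ±1 px; calibers of odd-width
  tubes are systematically half a pixel low (the discrete medial row is
  1 px, not 0.5 px, from the nearest outline row in a 3-row tube).
* The thin-scope evaluation region and the weighted-any reconstruction are
  package-level conventions (documented above), so absolute thin-scope
  numbers are comparable within this package, not across tools.
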