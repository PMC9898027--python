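# Methods

This note documents the models, parameter choices and numerical conventions
behind `reticulin_cif`, and what the synthetic experiments do and do not
demonstrate.

## Synthetic reticulin model

Real reticulin stains show a network of thin dark fibers on a bright
background, with severity expressed as increased fiber quantity, thickness
and crossing frequency. The generator reproduces these three cues from a
single latent per-pixel severity field `S ∈ [0,1]`:

* **Placement** — fiber midpoints follow a thinned Poisson process with
  acceptance probability `0.05 + 0.95·S(x)`, from a candidate intensity of
  `fiber_density` per megapixel (default 10 000). A fraction
  `bias/(1+bias)` of midpoints is resampled near already-placed fibers
  (`intersection_bias`, default 0.5), raising crossing frequency beyond
  independent placement.
* **Geometry** — straight segments, length ~ N(40, 12²) px, orientation
  uniform; per-fiber thickness ~ N(1.4·(0.6+0.8·S), 0.35²) px, truncated
  at 0.8, realized by dilating the rasterized centerline.
* **Appearance** — fibers at gray 45 on background 215, additive Gaussian
  noise (σ = 8), clipped 8-bit output. Painted over the fiber field:
  bright fat vacuoles (disks), a marginal bony trabecular band, and
  vessels, with mutually exclusive masks (priority bone > fat > vessel).
* **Hotspots** — disks of additively boosted severity (clipped at 1).
  Centers follow a Matérn-style parent/offspring rule: with probability
  `clustering/(1+clustering)` a center is drawn near an existing one,
  emulating spatially related microfoci.

The defaults were fixed by two physical considerations: a 128-px tile in
the scaled-down study geometry represents a ~113 µm field of view, which in
tissue holds on the order of 50–150 fiber segments (sparser fields degrade
the latent-to-appearance coupling to the point where severity is not
recoverable from a single tile, by any method — the realized fiber count is
too Poisson-noisy); and the tissue dark-pixel fraction should rise smoothly
with severity without saturating (defaults give 4%→43% over S = 0.05→0.9).

**What the generator does not emulate:** staining variation, counterstain
color, tissue tearing and edge artifacts, focus blur, non-linear
interactions between severity cues, osteosclerosis, and the morphological
continuity of real trabeculae. Passing tests therefore demonstrate that the
*algorithms* behave as specified under controlled conditions with known
ground truth — not that the trained scorer would transfer to clinical
slides.

## Study geometry

Library defaults follow the full-scale protocol (512-px tiles, 256-px
stride, 0.22 µm/px recorded as metadata). The bundled studies run a
4×-scaled-down geometry — 768×768 images, 128-px tiles, 64-px stride,
tiles reduced to 32×32 two-channel network inputs — preserving the 2:1
window:stride ratio and all filter thresholds. The two input channels per
4×4 block are the mean intensity and the fraction of pixels darker than 130
(midway between fiber and background gray); the second channel preserves
fiber-mass information that plain block averaging conflates with bright fat
or dark vessel regions.

## Ranking model and protocol

The backbone is deliberately small — two valid 3×3 convolution blocks
(8, 16 channels) with ReLU, 2×2 average pooling, global average pooling and
a linear head — implemented directly on numpy (im2col convolutions, manual
backprop, Adam at 2·10⁻³, batch 64). The method is the pairwise objective,
not the backbone: the loss is binary cross-entropy on
`P(a≻b) = σ(s_a − s_b)`, computed in softplus form for stability. Training
batches are augmented with random D4 symmetries (the fiber texture is
statistically isotropic).

The three-round protocol trains on 700 new pairs per round (uniform in
round 1, uncertainty-selected — smallest current |Δs| — afterwards),
always on the accumulated set, 20 epochs per round. Ranking accuracy is
evaluated after each round on a fixed held-out set of 800 uniformly sampled
pairs that never enters training. Uncertainty-selected pairs are excluded
from evaluation deliberately: they concentrate near score ties, where the
ordering is unlearnable noise for any scorer, so accuracy measured on them
reflects the selection rule rather than model quality. Pairs with exactly
equal model scores count 0.5 in accuracy. The training cohort spans the
severity spectrum (24 samples, base severity evenly spaced over
[0.03, 0.90] with jitter), the way ranking training sets are assembled from
biopsies chosen to cover the whole fibrosis range; every fourth sample is
held out so the Spearman check `ρ(CIF, latent severity)` measures transfer
to unseen images.

The learning-sanity study uses clean oracle labels; the noisy-annotator
path (three annotators, concordance 0.884, majority vote) has closed-form
expectations — inter-annotator agreement `p²+(1−p)² ≈ 0.795`, majority
accuracy `3p²(1−p)+p³` — that are verified directly, and is used in the
demo pipeline.

Score normalization is empirical min–max over the training reference tiles,
frozen afterwards, with clipping for out-of-range unseen tiles; it is the
simplest order-preserving map onto [0, 1].

## Features

Bin edges default to equal quarters of [0, 1]; the four bins broadly stand
in for MF-0…MF-3 and are configurable since no canonical edge set exists.
The last bin is closed at 1. Heterogeneity is `−Σ p_k ln p_k / ln 4`, so it
lies in [0, 1] regardless of bin count conventions. Excluded tiles are
never imputed. Overlay rendering averages the scores of all tiles covering
a pixel (symmetric and order-independent) before colorization.

## Topology

Persistence runs on the tile-score grid, one cell per tile. Conventions,
identical in the algorithms and the test oracle: 8-connected foreground
with the complementary 4-connected background; ties in cell values broken
by row-major index; elder rule at merges (higher birth survives, earlier
cell on ties); excluded tiles never enter the filtration, and holes caused
purely by them are reported as a separate mask-hole count (configurable).

Dimension 0 is a union-find sweep in descending score order. Dimension 1
exploits planar duality — holes of the 8-connected super-level set are
exactly the bounded 4-connected components of its complement — and runs the
component sweep on the complement in reversed filtration order: a hole is
born at the value where its surrounding cycle closes and dies at the value
of the last enclosed cell. This replaces boundary-matrix reduction, which
presumes a genuine cubical complex and does not match the 8-connectivity
convention; the dual sweep is exact for it. Both dimensions are validated
per-threshold against a brute-force flood-fill enumeration on small grids,
and zero-persistence (same-value) merges are not emitted as bars.

A *hotspot* is a dimension-0 bar born at or above the hotspot threshold
(default 0.5 — the lower edge of the moderate bin, since microfoci of
advanced fibrosis are precisely the tiles reaching that bin) with
persistence ≥ 0.1, the usual persistence-based denoising step. The full
`TopoFeatureVector` is a superset of plausible barcode statistics;
classification studies use the `TOPO_ARRANGEMENT_FEATURES` subset (bar and
hole counts, hotspot count, total/max persistences) because counts and
persistences describe how foci are arranged and separated and are invariant
to a uniform shift of the score level, complementing rather than
duplicating the marginal features; mean births and persistence entropies
track the overall level and mostly echo them.

## Cohort analysis

Features are z-scored before PCA, with means, scales and component signs
(largest-magnitude loading positive) frozen at fit so that indexing new or
sequential samples is stable. The classifier is a 100-tree random forest
under seeded, stratified 3-fold cross-validation; the headline AUC pools
out-of-fold probabilities, per-fold AUCs are reported alongside, and Gini
importances come from a refit on all samples. Group comparisons use the
exact Mann–Whitney null for tie-free groups of ≤ 20, otherwise the
tie-corrected normal approximation; Bonferroni multiplies by an explicit
`n_comparisons`, never an inferred one; median CIs are distribution-free
order-statistic intervals at ≥ 95% coverage (the sample range when that
coverage is unattainable at the sample size).

## The hotspot-discrimination experiment

The two-class study behind the topology claim is a controlled experiment:
both classes share the same diffuse base severity (0.14) and the same
expected total focal area, and differ only in hotspot prevalence — an
occasional single large focus (Poisson(1), radius 150 px) versus several
smaller clustered microfoci (Poisson(4.2), radius 75 px, clustered). With
the focal area matched, marginal features (average, bins, heterogeneity)
overlap between classes and the separating information is the *number and
arrangement* of foci. Focus radii are at least 75 px so that a focus fully
covers at least one tile; smaller foci are systematically invisible at tile
resolution (partial-volume effect). If instead the classes differ in focal
area, bin fractions see that difference directly and with less noise than
any count statistic, and topology cannot add value — a useful negative
result to keep in mind when interpreting the corresponding clinical claim.

## Problem sizes and determinism

The bundled studies use 24-sample training cohorts, ~2,100 training pairs
over three rounds, and ten 60-sample cohorts for the discrimination
experiment; the full test suite runs in about six minutes and the
reproduction script in about ten on one CPU. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical seeds
give bit-identical synthetic samples and training trajectories.

## Known limitations

* The scorer is validated on synthetic texture only; no claim is made about
  clinical transfer, and the cohort-specific accuracies and AUCs of any
  clinical deployment are out of reach by construction.
* Severity composes additively (base + disks); real focal fibrosis also
  changes texture anisotropy and architecture.
* Dimension-1 features on the tile grid are coarse: a hole needs a ring of
  high-scoring tiles around a low-scoring region at least one tile wide.
* The annotator model flips labels independently of pair difficulty; real
  expert disagreement concentrates on close calls (the expected accuracy
  against labels is unchanged, but per-pair error patterns differ).
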