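# reticulin-cif

Continuous Indexing of Fibrosis (CIF) for reticulin-stained bone marrow
trephine images.

Bone marrow fibrosis — the pathological accumulation of reticulin (type-III
collagen) fibers in the marrow stroma — is graded in routine practice on the
coarse ordinal WHO scale MF-0…MF-3. That scale hides focal disease,
within-sample heterogeneity and early progression, all of which matter in
myeloproliferative neoplasms (MPN: ET, PV, pre-PMF, PMF/MF). This package
implements a continuous alternative for pathologists and computational
researchers: every 512×512 image tile receives a score in [0, 1] from a
model trained purely on *pairwise* expert comparisons ("which of these two
regions is more fibrotic?"), and per-sample score maps are summarized,
topologically analyzed and embedded for cohort-level comparison.

## The method

**Ranking objective.** A convolutional scorer maps a grayscale tile to a raw
scalar *s*. The probability that tile *a* outranks tile *b* is modeled as

    P(a ≻ b) = σ(s_a − s_b) = 1 / (1 + exp(−(s_a − s_b))),

trained by cross-entropy on pairwise labels (the RankNet objective). Labels
come from a panel of annotators simulated at a configurable concordance with
majority voting; rounds of training alternate with model-guided pair
selection (uncertainty sampling). Raw scores are min–max normalized on a
reference tile set to the CIF scale, 1 = most fibrotic.

**Tiling and filters.** Images are converted to grayscale (Rec.601),
tiled by a sliding window (512 px, stride 256 by default) and a tile enters
the analysis only when fat < 50%, bone < 1% and vessel < 10% of its area
(strict inequalities), restricting scoring to areas of hematopoiesis.

**Per-sample features.** From a sample's CIF map: the average CIF; the tile
distribution over four bins broadly corresponding to MF-0…MF-3 (default
edges 0, 0.25, 0.5, 0.75, 1); and heterogeneity, the Shannon entropy of the
bin distribution normalized by ln 4.

**Topology of hotspots.** The super-level sets {tile score ≥ t} of a CIF
map, swept from high t downward, form a filtration whose persistent
homology is computed exactly (union-find with the elder rule for connected
components; the dual sweep on the 4-connected complement for holes, with
8-connected foreground). Barcode statistics — number of fibrotic foci above
a severity threshold, persistences, hole counts — quantify how focal
fibrosis is arranged, information invisible to marginal summaries.

**Cohort space.** Feature vectors are z-scored and embedded by 2-D PCA
("disease space") with frozen standardization so sequential biopsies can be
indexed into the same coordinates; groups are compared by two-sided
Mann–Whitney–Wilcoxon tests with Bonferroni adjustment and order-statistic
median CIs; diagnostic groups are discriminated by a 100-tree random forest
under stratified 3-fold cross-validation with Gini importances.

Because clinical trephine scans are not redistributable, the package ships
a seeded synthetic reticulin generator (`reticulin_cif.synthetic`): fiber
networks whose density, thickness and crossing frequency increase with a
latent per-pixel severity field, plus fat vacuoles, bony trabeculae,
vessels and clustered severity hotspots. The latent field is the ground
truth that every stage is tested against.

## Worked example

Score a synthetic pre-PMF-like sample (diffuse severity 0.12 plus three
focal hotspots) with a trained ranking model:

```python
import numpy as np
from reticulin_cif import (
    FiberFieldParams, HotspotSpec, generate_sample, extract_grid,
    apply_filters, build_cif_map, feature_vector, barcode, Filtration,
    barcode_features,
)
from reticulin_cif.pipeline import train_demo_ranker

model = train_demo_ranker(seed=7)["model"]   # ~2 min on one CPU

sample = generate_sample(
    FiberFieldParams(seed=11),
    hotspots=HotspotSpec(count=3, radius_px=85, severity_boost=0.45),
    shape=(768, 768), base_severity=0.12,
    class_label="prePMF-like", sample_id="demo",
)
grid = apply_filters(extract_grid(sample.image.shape, 128, 64), sample.layout)
cif_map = build_cif_map(model, grid, sample.image)
fv = feature_vector(cif_map, "demo", "prePMF-like")
print(f"tiles included: {fv.n_tiles} / {len(grid.tiles)}")
print(f"average CIF:    {fv.avg_cif:.3f}")
print(f"bin fractions:  {np.round(fv.bin_fracs, 3)}")
print(f"heterogeneity:  {fv.heterogeneity:.3f}")
topo = barcode_features(barcode(Filtration(cif_map.scores)), hotspot_threshold=0.5)
print(f"hotspots: {topo.n_hotspots}, max persistence: {topo.max_persistence_dim0:.3f}")
```

Output:

```
tiles included: 97 / 121
average CIF:    0.256
bin fractions:  [0.68  0.247 0.072 0.   ]
heterogeneity:  0.575
hotspots: 2, max persistence: 0.212
```

Reading it: 24 of 121 tiles were rejected by the fat/bone/vessel filters;
the sample is mildly fibrotic on average (0.256) but 7% of its tiles reach
the moderate bin — those are the focal hotspots, two of which survive as
distinct high-persistence components in the barcode (the third overlaps a
filtered region).

## Command line

The `cif` tool chains the stages: `cif simulate`, `cif tile`,
`cif train-ranker`, `cif score`, `cif features`, `cif tda`, `cif index`,
`cif classify`, `cif compare`, `cif run`. For example:

```bash
cif simulate --out cohort/ --seed 7 --n-per-class 3
cif run --out results/ --seed 7
```

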