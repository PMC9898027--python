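"""Seeded synthetic reticulin-stained-like images with ground-truth severity.

Reticulin fibrosis appears on silver-stained bone marrow trephine sections as
a network of dark linear fibers; severity manifests as increased fiber
quantity, thickness and intersection frequency. This module draws such fiber
networks on a bright background, modulated everywhere by a latent per-pixel
severity field in [0, 1] that downstream stages treat as ground truth. On top
of the fiber field it places the non-analyzable tissue elements a trephine
contains — bright fat vacuoles, bony trabeculae and blood vessels — and
returns their masks, so the tile-inclusion filters have something to filter.

Severity is the single source of truth: local fiber placement rate, fiber
thickness and (via density) crossing frequency are all non-decreasing
functions of the local severity value, and "hotspots" are disks of additively
boosted severity mimicking microfoci of advanced fibrosis. Appearance is
derived from severity, never the other way round, which is what makes
parameter-recovery experiments possible.

Everything is driven by ``numpy.random.default_rng`` seeded from explicit
integers: identical seed and parameters give bit-identical samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import InvalidArgumentError, OutOfBoundsError

CLASS_LABELS = ("reactive", "ET-like", "PV-like", "prePMF-like", "MF-like")

A_MORE_SEVERE = "a_more_severe"
B_MORE_SEVERE = "b_more_severe"


@dataclass(frozen=True)
class FiberFieldParams:
    """Knobs of the fiber network renderer.

    fiber_density is the expected number of fibers per megapixel at severity
    1; the local placement rate scales down with severity (thinned Poisson
    process). Thickness is drawn per fiber from a truncated normal whose mean
    grows with local severity. intersection_bias >= 0 biases fiber midpoints
    toward existing fibers so crossings become more frequent than for
    independent placement. Fibers are dark on a bright background
    (fiber_gray < background_gray).
    """

    fiber_density: float = 10000.0
    thickness_mean: float = 1.4
    thickness_sd: float = 0.35
    intersection_bias: float = 0.5
    background_gray: int = 215
    fiber_gray: int = 45
    fiber_length_mean: float = 40.0
    fiber_length_sd: float = 12.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fiber_density < 0:
            raise InvalidArgumentError("fiber_density must be >= 0")
        if self.thickness_mean <= 0:
            raise InvalidArgumentError("thickness_mean must be > 0")
        if self.intersection_bias < 0:
            raise InvalidArgumentError("intersection_bias must be >= 0")
        if not self.fiber_gray < self.background_gray:
            raise InvalidArgumentError(
                "fiber_gray must be < background_gray (fibers are dark)"
            )


@dataclass(frozen=True)
class HotspotSpec:
    """Disks of additively boosted severity (microfoci of advanced fibrosis).

    clustering = 0 places hotspot centers uniformly; larger values place
    later hotspots preferentially near earlier ones (parent/offspring style),
    emulating spatially related fibrotic foci.
    """

    count: int = 0
    radius_px: float = 96.0
    severity_boost: float = 0.45
    clustering: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise InvalidArgumentError("hotspot count must be >= 0")
        if not 0.0 <= self.severity_boost <= 1.0:
            raise InvalidArgumentError("severity_boost must lie in [0, 1]")
        if self.clustering < 0:
            raise InvalidArgumentError("clustering must be >= 0")


@dataclass(frozen=True)
class LayoutParams:
    """Target area fractions of non-analyzable tissue elements."""

    fat_frac: float = 0.08
    bone_frac: float = 0.04
    vessel_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("fat_frac", "bone_frac", "vessel_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1]")
        if self.fat_frac + self.bone_frac + self.vessel_frac > 1.0:
            raise InvalidArgumentError("mask fractions sum to more than 1")


@dataclass
class TissueLayout:
    """Mutually exclusive binary masks for fat, bone, vessel and tissue."""

    fat_mask: np.ndarray
    bone_mask: np.ndarray
    vessel_mask: np.ndarray
    tissue_mask: np.ndarray

    def validate(self) -> None:
        shp = self.fat_mask.shape
        for m in (self.bone_mask, self.vessel_mask, self.tissue_mask):
            if m.shape != shp:
                raise InvalidArgumentError("layout masks differ in shape")
        overlap = (
            (self.fat_mask & self.bone_mask)
            | (self.fat_mask & self.vessel_mask)
            | (self.bone_mask & self.vessel_mask)
        )
        if overlap.any():
            raise InvalidArgumentError("layout masks overlap")


@dataclass
class SyntheticSample:
    """A synthetic trephine-like image with its latent ground truth."""

    image: np.ndarray
    layout: TissueLayout
    severity_field: np.ndarray
    class_label: str
    seed: int
    params: FiberFieldParams | None = None
    hotspots: HotspotSpec | None = None
    sample_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


def _hotspot_centers(
    spec: HotspotSpec, shape: tuple[int, int], rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Matérn-style placement: offspring centers cluster near parents."""
    h, w = shape
    centers: list[tuple[float, float]] = []
    for _ in range(spec.count):
        p_cluster = spec.clustering / (1.0 + spec.clustering)
        if centers and rng.random() < p_cluster:
            pr, pc = centers[rng.integers(len(centers))]
            r = pr + rng.normal(0, 2.0 * spec.radius_px)
            c = pc + rng.normal(0, 2.0 * spec.radius_px)
            r = float(np.clip(r, 0, h - 1))
            c = float(np.clip(c, 0, w - 1))
        else:
            r = float(rng.uniform(0, h - 1))
            c = float(rng.uniform(0, w - 1))
        centers.append((r, c))
    return centers


def build_severity_field(
    shape: tuple[int, int],
    base_severity: float | np.ndarray,
    hotspots: HotspotSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent severity = clip(base + hotspot boosts, 0, 1)."""
    h, w = shape
    sev = np.broadcast_to(np.asarray(base_severity, dtype=np.float64), (h, w)).copy()
    if hotspots.count > 0:
        rr, cc = np.mgrid[0:h, 0:w]
        for cr, ccen in _hotspot_centers(hotspots, shape, rng):
            disk = (rr - cr) ** 2 + (cc - ccen) ** 2 <= hotspots.radius_px**2
            sev[disk] += hotspots.severity_boost
    return np.clip(sev, 0.0, 1.0)


def _generate_layout(
    shape: tuple[int, int], layout_params: LayoutParams, rng: np.random.Generator
) -> TissueLayout:
    """Fat vacuoles as disks, bone as a marginal band, vessels as annuli.

    Priority bone > fat > vessel keeps the masks mutually exclusive.
    """
    h, w = shape
    area = h * w
    rr, cc = np.mgrid[0:h, 0:w]

    bone = np.zeros(shape, dtype=bool)
    if layout_params.bone_frac > 0:
        # one wavy trabecular band along a random edge
        width = max(2, int(round(layout_params.bone_frac * area / max(h, w))))
        edge = rng.integers(4)
        wave = width * 0.3 * np.sin(np.arange(max(h, w)) / 37.0 + rng.uniform(0, 6))
        if edge == 0:
            bone[rr < width + wave[cc]] = True
        elif edge == 1:
            bone[rr > h - 1 - width - wave[cc]] = True
        elif edge == 2:
            bone[cc < width + wave[rr]] = True
        else:
            bone[cc > w - 1 - width - wave[rr]] = True

    fat = np.zeros(shape, dtype=bool)
    target_fat = layout_params.fat_frac * area
    mean_r = max(4.0, np.sqrt(area) / 40.0)
    guard = 0
    while fat.sum() < target_fat and guard < 10_000:
        guard += 1
        r = rng.uniform(0.5 * mean_r, 1.8 * mean_r)
        yc, xc = rng.uniform(0, h), rng.uniform(0, w)
        disk = (rr - yc) ** 2 + (cc - xc) ** 2 <= r * r
        fat |= disk
    fat &= ~bone

    vessel = np.zeros(shape, dtype=bool)
    target_vessel = layout_params.vessel_frac * area
    guard = 0
    while vessel.sum() < target_vessel and guard < 10_000:
        guard += 1
        r_out = rng.uniform(1.2 * mean_r, 2.5 * mean_r)
        yc, xc = rng.uniform(0, h), rng.uniform(0, w)
        d2 = (rr - yc) ** 2 + (cc - xc) ** 2
        vessel |= d2 <= r_out * r_out
    vessel &= ~bone & ~fat

    tissue = ~(fat | bone | vessel)
    layout = TissueLayout(fat, bone, vessel, tissue)
    layout.validate()
    return layout


def _draw_fibers(
    shape: tuple[int, int],
    params: FiberFieldParams,
    severity: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render the fiber network as a boolean mask.

    Fibers are straight segments; midpoints follow a severity-thinned Poisson
    process (rate multiplier 0.05 + 0.95*s), with a fraction
    bias/(1+bias) of midpoints resampled near already-placed fibers so that
    crossings grow with intersection_bias. Thickness per fiber is a truncated
    normal whose mean scales as (0.6 + 0.8*s) * thickness_mean.
    """
    h, w = shape
    mask_by_radius: dict[int, np.ndarray] = {}
    n_candidates = rng.poisson(params.fiber_density * h * w / 1e6)
    accepted: list[tuple[float, float]] = []
    p_near = params.intersection_bias / (1.0 + params.intersection_bias)
    for _ in range(n_candidates):
        if accepted and rng.random() < p_near:
            ar, ac = accepted[rng.integers(len(accepted))]
            my = float(np.clip(ar + rng.normal(0, params.fiber_length_mean / 3), 0, h - 1))
            mx = float(np.clip(ac + rng.normal(0, params.fiber_length_mean / 3), 0, w - 1))
        else:
            my, mx = float(rng.uniform(0, h - 1)), float(rng.uniform(0, w - 1))
        s_local = float(severity[int(my), int(mx)])
        if rng.random() > 0.05 + 0.95 * s_local:
            continue
        accepted.append((my, mx))
        length = max(4.0, rng.normal(params.fiber_length_mean, params.fiber_length_sd))
        theta = rng.uniform(0, np.pi)
        dy, dx = 0.5 * length * np.sin(theta), 0.5 * length * np.cos(theta)
        y0, x0 = int(round(my - dy)), int(round(mx - dx))
        y1, x1 = int(round(my + dy)), int(round(mx + dx))
        thick = rng.normal(
            params.thickness_mean * (0.6 + 0.8 * s_local), params.thickness_sd
        )
        thick = max(0.8, thick)
        radius = max(0, int(round((thick - 1.0) / 2.0)))
        m = mask_by_radius.setdefault(radius, np.zeros(shape, dtype=bool))
        _draw_line(m, y0, x0, y1, x1)

    fibers = np.zeros(shape, dtype=bool)
    for radius, m in mask_by_radius.items():
        if radius > 0:
            yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
            footprint = yy * yy + xx * xx <= radius * radius
            m = ndimage.binary_dilation(m, structure=footprint)
        fibers |= m
    return fibers


def _draw_line(mask: np.ndarray, y0: int, x0: int, y1: int, x1: int) -> None:
    """Rasterize a clipped segment into mask (dense sampling, no deps)."""
    h, w = mask.shape
    n = int(max(abs(y1 - y0), abs(x1 - x0))) + 1
    ys = np.rint(np.linspace(y0, y1, n)).astype(np.intp)
    xs = np.rint(np.linspace(x0, x1, n)).astype(np.intp)
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    mask[ys[keep], xs[keep]] = True


def generate_sample(
    params: FiberFieldParams,
    hotspots: HotspotSpec | None = None,
    layout_params: LayoutParams | None = None,
    shape: tuple[int, int] = (768, 768),
    base_severity: float | np.ndarray = 0.2,
    class_label: str = "reactive",
    sample_id: str = "",
) -> SyntheticSample:
    """Generate one synthetic reticulin-like sample.

    Parameters
    ----------
    params
        Fiber network parameters; ``params.seed`` drives all randomness.
    hotspots
        Spec for severity-boosted disks; ``None`` means no hotspots.
    layout_params
        Target fat/bone/vessel area fractions; ``None`` uses defaults.
    shape
        Image extent in pixels (rows, cols).
    base_severity
        Scalar or per-pixel array added below the hotspot boosts; the final
        latent field is clipped to [0, 1].
    """
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise InvalidArgumentError(f"shape must be positive 2-D, got {shape!r}")
    if class_label not in CLASS_LABELS:
        raise InvalidArgumentError(
            f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    hotspots = hotspots if hotspots is not None else HotspotSpec(count=0)
    layout_params = layout_params if layout_params is not None else LayoutParams()

    rng = np.random.default_rng(params.seed)
    severity = build_severity_field(shape, base_severity, hotspots, rng)
    layout = _generate_layout(shape, layout_params, rng)
    fibers = _draw_fibers(shape, params, severity, rng)

    img = np.full(shape, float(params.background_gray))
    img[fibers] = float(params.fiber_gray)
    # non-analyzable elements are painted over the fiber field
    img[layout.fat_mask] = 243.0
    img[layout.bone_mask] = 130.0
    img[layout.vessel_mask] = 95.0
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SyntheticSample(
        image=image,
        layout=layout,
        severity_field=severity,
        class_label=class_label,
        seed=params.seed,
        params=params,
        hotspots=hotspots,
        sample_id=sample_id,
    )


@dataclass(frozen=True)
class ClassSpec:
    """Distribution of generator parameters for one disease-like class."""

    base_severity_mean: float
    base_severity_sd: float
    hotspot_count_mean: float = 0.0
    hotspot_radius_px: float = 96.0
    hotspot_boost: float = 0.45
    hotspot_clustering: float = 0.0


# Study conditions for the synthetic cohort. The classes mirror the clinical
# ordering of diffuse marrow fibrosis severity: reactive < ET < (PV, pre-PMF)
# < MF. Focal fibrosis is graded, not binary: ET-like marrows carry an
# occasional mild focus (focal fibrosis in ET seldom exceeds low-grade
# change), while pre-PMF-like marrows share a similar diffuse background but
# carry several stronger, spatially clustered microfoci of advanced
# fibrosis, so the realized hotspot loads of the two classes overlap and
# their separation is a matter of prevalence and arrangement rather than
# presence versus absence.
DEFAULT_CLASS_SPECS: dict[str, ClassSpec] = {
    "reactive": ClassSpec(0.05, 0.02),
    "ET-like": ClassSpec(
        0.15, 0.04, hotspot_count_mean=1.0, hotspot_radius_px=72.0,
        hotspot_boost=0.35,
    ),
    "PV-like": ClassSpec(
        0.30, 0.06, hotspot_count_mean=1.5, hotspot_radius_px=88.0,
        hotspot_boost=0.35, hotspot_clustering=0.5,
    ),
    "prePMF-like": ClassSpec(
        0.13, 0.04, hotspot_count_mean=3.5, hotspot_radius_px=88.0,
        hotspot_boost=0.45, hotspot_clustering=1.5,
    ),
    "MF-like": ClassSpec(
        0.55, 0.08, hotspot_count_mean=2.0, hotspot_boost=0.35,
        hotspot_clustering=0.5,
    ),
}


def generate_cohort(
    class_specs: dict[str, ClassSpec] | None = None,
    n_per_class: int = 5,
    seed: int = 0,
    shape: tuple[int, int] = (768, 768),
    fiber_params: FiberFieldParams | None = None,
    layout_params: LayoutParams | None = None,
) -> list[SyntheticSample]:
    """Generate n_per_class samples per class with per-sample derived seeds."""
    if n_per_class < 1:
        raise InvalidArgumentError("n_per_class must be >= 1")
    class_specs = class_specs if class_specs is not None else DEFAULT_CLASS_SPECS
    for label in class_specs:
        if label not in CLASS_LABELS:
            raise InvalidArgumentError(f"unknown class label {label!r}")
    base_params = fiber_params if fiber_params is not None else FiberFieldParams()
    master = np.random.default_rng(seed)
    samples: list[SyntheticSample] = []
    for label, spec in class_specs.items():
        for i in range(n_per_class):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            base = float(
                np.clip(rng.normal(spec.base_severity_mean, spec.base_severity_sd), 0, 1)
            )
            count = int(rng.poisson(spec.hotspot_count_mean))
            hs = HotspotSpec(
                count=count,
                radius_px=spec.hotspot_radius_px,
                severity_boost=spec.hotspot_boost,
                clustering=spec.hotspot_clustering,
            )
            params = replace(base_params, seed=sub_seed)
            samples.append(
                generate_sample(
                    params,
                    hotspots=hs,
                    layout_params=layout_params,
                    shape=shape,
                    base_severity=base,
                    class_label=label,
                    sample_id=f"{label}_{i:03d}",
                )
            )
    return samples


def generate_spectrum_cohort(
    n_samples: int = 24,
    seed: int = 0,
    shape: tuple[int, int] = (768, 768),
    fiber_params: FiberFieldParams | None = None,
    severity_range: tuple[float, float] = (0.03, 0.90),
    layout_params: LayoutParams | None = None,
) -> list[SyntheticSample]:
    """Training cohort spanning the fibrosis spectrum.

    Base severities are spread evenly (with seeded jitter) across
    severity_range, each sample carrying a Poisson(1) number of hotspots —
    the analogue of assembling a ranking-model training set from biopsies
    deliberately chosen to cover the whole range of marrow fibrosis.
    Class labels are assigned from the base severity for bookkeeping only.
    """
    if n_samples < 2:
        raise InvalidArgumentError("n_samples must be >= 2")
    base_params = fiber_params if fiber_params is not None else FiberFieldParams()
    master = np.random.default_rng(seed)
    lo, hi = severity_range
    grid_vals = np.linspace(lo, hi, n_samples)
    step = (hi - lo) / max(1, n_samples - 1)
    samples = []
    for i, g in enumerate(grid_vals):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        base = float(np.clip(g + rng.uniform(-0.4, 0.4) * step, 0.0, 1.0))
        hs = HotspotSpec(count=int(rng.poisson(1.0)), clustering=0.5)
        label = (
            "reactive" if base < 0.10
            else "ET-like" if base < 0.25
            else "PV-like" if base < 0.45
            else "prePMF-like" if base < 0.60
            else "MF-like"
        )
        samples.append(
            generate_sample(
                replace(base_params, seed=sub_seed),
                hotspots=hs,
                layout_params=layout_params,
                shape=shape,
                base_severity=base,
                class_label=label,
                sample_id=f"spectrum_{i:03d}",
            )
        )
    return samples


def severity_oracle(tile_a, tile_b, sample: SyntheticSample) -> str:
    """Ground-truth ordering of two tiles by mean latent severity.

    Stands in for an expert choosing the more severe of two image regions.
    Exact ties resolve to ``a_more_severe`` (deterministic, documented).
    """
    h, w = sample.severity_field.shape
    means = []
    for t in (tile_a, tile_b):
        r0, c0, size = t.row0, t.col0, t.size
        if r0 < 0 or c0 < 0 or r0 + size > h or c0 + size > w:
            raise OutOfBoundsError(
                f"tile at ({r0}, {c0}) size {size} lies outside {h}x{w} image"
            )
        means.append(float(sample.severity_field[r0 : r0 + size, c0 : c0 + size].mean()))
    return A_MORE_SEVERE if means[0] >= means[1] else B_MORE_SEVERE


def write_sample(sample: SyntheticSample, directory: str | Path) -> dict[str, Path]:
    """Write image, masks and a JSON metadata sidecar; returns written paths."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = sample.sample_id or "sample"
    paths: dict[str, Path] = {}

    paths["image"] = directory / f"{sid}.png"
    Image.fromarray(sample.image, mode="L").save(paths["image"])
    for name, mask in (
        ("fat", sample.layout.fat_mask),
        ("bone", sample.layout.bone_mask),
        ("vessel", sample.layout.vessel_mask),
        ("tissue", sample.layout.tissue_mask),
    ):
        p = directory / f"{sid}_{name}.png"
        Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(p)
        paths[name] = p

    meta = {
        "sample_id": sid,
        "class_label": sample.class_label,
        "seed": sample.seed,
        "shape": list(sample.image.shape),
    }
    if sample.params is not None:
        meta["fiber_params"] = {
            k: getattr(sample.params, k)
            for k in (
                "fiber_density",
                "thickness_mean",
                "thickness_sd",
                "intersection_bias",
                "background_gray",
                "fiber_gray",
                "noise_sd",
                "seed",
            )
        }
    paths["meta"] = directory / f"{sid}.json"
    paths["meta"].write_text(json.dumps(meta, indent=1))
    paths["severity"] = directory / f"{sid}_severity.npy"
    np.save(paths["severity"], sample.severity_field)
    return paths


def load_cohort(manifest_path: str | Path) -> list[SyntheticSample]:
    """Rehydrate a cohort written by write_cohort_manifest."""
    import csv

    from PIL import Image

    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    samples: list[SyntheticSample] = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(directory / row["image"]))
            masks = {}
            for key in ("fat_mask", "bone_mask", "vessel_mask"):
                masks[key] = np.asarray(Image.open(directory / row[key])) > 127
            tissue = ~(masks["fat_mask"] | masks["bone_mask"] | masks["vessel_mask"])
            sev_path = directory / f"{row['sample_id']}_severity.npy"
            severity = (
                np.load(sev_path) if sev_path.exists() else np.zeros_like(image, dtype=float)
            )
            meta = json.loads((directory / f"{row['sample_id']}.json").read_text())
            samples.append(
                SyntheticSample(
                    image=image,
                    layout=TissueLayout(
                        masks["fat_mask"], masks["bone_mask"], masks["vessel_mask"], tissue
                    ),
                    severity_field=severity,
                    class_label=row["class"],
                    seed=int(meta.get("seed", 0)),
                    sample_id=row["sample_id"],
                )
            )
    return samples


def write_cohort_manifest(
    samples: list[SyntheticSample], directory: str | Path
) -> Path:
    """Write all samples plus a manifest CSV (sample_id, class, paths)."""
    import csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "class", "image", "fat_mask", "bone_mask", "vessel_mask"]
        )
        for s in samples:
            paths = write_sample(s, directory)
            writer.writerow(
                [
                    s.sample_id,
                    s.class_label,
                    paths["image"].name,
                    paths["fat"].name,
                    paths["bone"].name,
                    paths["vessel"].name,
                ]
            )
    return manifest
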