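"""Persistent homology of super-level sets of a CIF map.

The filtration sweeps a threshold t from the maximum score downward; the
super-level set at t is the set of grid cells with score >= t. As t falls,
fibrotic hotspots appear as connected components (dimension 0), merge with
their neighbors, and rings of high scores around low-score cells create
one-dimensional holes (dimension 1). Each feature is a bar (birth, death)
with birth >= death on this descending scale; components alive when every
cell has entered are open (infinite) bars.

Conventions, applied identically in the main algorithms and the test
oracle:

* foreground (super-level) cells are 8-connected, so the complement is
  4-connected — the standard complementary pair on a pixel grid;
* ties between cell values are broken by row-major cell index, giving a
  total order;
* at a component merge the elder rule applies: the component with the
  higher birth survives (tie -> earlier birth cell in the total order);
* excluded cells (NaN) never enter the filtration. Holes whose interior
  contains an excluded cell persist past the end of the sweep; by default
  they are reported separately as mask holes rather than as H1 bars.

Dimension 0 is a direct union-find sweep in descending order. Dimension 1
uses planar duality: holes of the 8-connected foreground are exactly the
bounded 4-connected components of the complement, so the H1 barcode is
computed by running the component sweep on the complement in reversed
filtration order (a hole is born when its surrounding cycle closes and dies
when its enclosed cells have all entered). Both are validated against a
brute-force per-threshold flood-fill oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, InvalidArgumentError

OPEN = None  # death value of an infinite bar


@dataclass(frozen=True)
class Bar:
    dim: int
    birth: float
    death: float | None  # None = OPEN (infinite)
    birth_cell: tuple[int, int] | None = None

    @property
    def is_open(self) -> bool:
        return self.death is None

    @property
    def persistence(self) -> float:
        if self.death is None:
            return float("inf")
        return self.birth - self.death


@dataclass
class Barcode:
    bars: list[Bar]
    grid_shape: tuple[int, int]
    connectivity: int = 8
    n_mask_holes: int = 0

    def dim(self, d: int) -> list[Bar]:
        return [b for b in self.bars if b.dim == d]

    def as_dataframe(self, sample_id: str = "") -> pd.DataFrame:
        rows = [
            {
                "sample_id": sample_id,
                "dim": b.dim,
                "birth": b.birth,
                "death": "inf" if b.is_open else b.death,
                "birth_row": b.birth_cell[0] if b.birth_cell else -1,
                "birth_col": b.birth_cell[1] if b.birth_cell else -1,
            }
            for b in self.bars
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "dim", "birth", "death", "birth_row", "birth_col"]
        )


@dataclass
class Filtration:
    """Super-level-set filtration of a 2-D score grid (NaN = excluded)."""

    values: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidArgumentError("filtration values must be a 2-D grid")
        if self.connectivity not in (4, 8):
            raise InvalidArgumentError("connectivity must be 4 or 8")


_NEIGHBORS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_NEIGHBORS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


class _UnionFind:
    """Union-find with per-root payload (birth value, birth order index)."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.birth_value = np.empty(n)
        self.birth_order = np.empty(n, dtype=np.int64)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return int(root)

    def elder(self, ra: int, rb: int) -> tuple[int, int]:
        """Return (survivor_root, dying_root) by the elder rule."""
        ka = (self.birth_value[ra], -self.birth_order[ra])
        kb = (self.birth_value[rb], -self.birth_order[rb])
        return (ra, rb) if ka >= kb else (rb, ra)


def h0_barcode(filtration: Filtration) -> list[Bar]:
    """Dimension-0 bars of the descending sweep (elder rule at merges)."""
    vals = filtration.values
    h, w = vals.shape
    finite = np.isfinite(vals)
    if not finite.any():
        raise DataError("all cells excluded: empty filtration")
    neighbors = _NEIGHBORS_8 if filtration.connectivity == 8 else _NEIGHBORS_4

    cells = np.flatnonzero(finite.ravel())
    # descending value, ties by row-major index
    order = cells[np.lexsort((cells, -vals.ravel()[cells]))]
    uf = _UnionFind(h * w)
    added = np.zeros(h * w, dtype=bool)
    bars: list[Bar] = []

    for k, c in enumerate(order):
        c = int(c)
        v = vals.ravel()[c]
        uf.birth_value[c] = v
        uf.birth_order[c] = k
        added[c] = True
        r, cc = divmod(c, w)
        for dr, dc in neighbors:
            nr, nc = r + dr, cc + dc
            if not (0 <= nr < h and 0 <= nc < w):
                continue
            n = nr * w + nc
            if not added[n]:
                continue
            ra, rb = uf.find(c), uf.find(n)
            if ra == rb:
                continue
            survivor, dying = uf.elder(ra, rb)
            if uf.birth_value[dying] > v:
                # same-value merges are ephemeral (zero persistence), not features
                bars.append(
                    Bar(
                        dim=0,
                        birth=float(uf.birth_value[dying]),
                        death=float(v),
                        birth_cell=_order_cell(order, uf.birth_order[dying], w),
                    )
                )
            uf.parent[dying] = survivor

    roots = {uf.find(int(c)) for c in order}
    for root in sorted(roots, key=lambda rt: uf.birth_order[rt]):
        bars.append(
            Bar(
                dim=0,
                birth=float(uf.birth_value[root]),
                death=OPEN,
                birth_cell=_order_cell(order, uf.birth_order[root], w),
            )
        )
    return bars


def _order_cell(order: np.ndarray, order_idx: int, w: int) -> tuple[int, int]:
    flat = int(order[int(order_idx)])
    return (flat // w, flat % w)


def h1_barcode(filtration: Filtration, include_mask_holes: bool = False) -> list[Bar]:
    bars, _ = _h1_sweep(filtration, include_mask_holes)
    return bars


def _h1_sweep(filtration: Filtration, include_mask_holes: bool) -> tuple[list[Bar], int]:
    """Dimension-1 bars via the dual sweep on the 4-connected complement.

    Reversing time, complement cells enter in ascending value order; a
    bounded complement component that merges into the outside at value v
    corresponds to a hole born at v, and the value at which that component
    first appeared is the hole's death. A merge of two bounded components
    at v splits one hole into two going forward; the elder rule pairs the
    younger (higher first-entry value) component's bar. Components seeded by
    excluded cells yield holes that never die: mask holes, emitted as OPEN
    bars only when include_mask_holes is set.
    """
    vals = filtration.values
    h, w = vals.shape
    finite = np.isfinite(vals)
    if not finite.any():
        raise DataError("all cells excluded: empty filtration")
    if filtration.connectivity != 8:
        raise InvalidArgumentError(
            "dimension-1 duality is implemented for 8-connected foreground"
        )

    OUTSIDE = h * w  # virtual node for the unbounded complement region
    parent = list(range(h * w + 1))
    rbirth = [np.inf] * (h * w + 1)  # first-entry value per component root
    is_mask = [False] * (h * w + 1)
    rbirth[OUTSIDE] = -np.inf
    added = np.zeros(h * w + 1, dtype=bool)
    added[OUTSIDE] = True

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    # reverse of the forward order (descending value, row-major ties):
    # ascending value, ties by descending row-major index; excluded first
    flat = vals.ravel()
    excluded = np.flatnonzero(~finite.ravel())
    fin = np.flatnonzero(finite.ravel())
    fin_order = fin[np.lexsort((-fin, flat[fin]))]
    entry_order = np.concatenate([excluded[::-1], fin_order])
    entry_value = np.where(np.isfinite(flat), flat, -np.inf)

    bars: list[Bar] = []
    n_mask_holes = 0

    for c in entry_order:
        c = int(c)
        v = entry_value[c]
        rbirth[c] = v
        is_mask[c] = not np.isfinite(vals.ravel()[c])
        added[c] = True
        r, cc = divmod(c, w)
        for dr, dc in _NEIGHBORS_4:
            nr, nc = r + dr, cc + dc
            if 0 <= nr < h and 0 <= nc < w:
                n = nr * w + nc
            else:
                n = OUTSIDE
            if not added[n]:
                continue
            ra, rb = find(c), find(n)
            if ra == rb:
                continue
            # elder: smaller first-entry value survives; OUTSIDE is eldest
            if ra == OUTSIDE or (rb != OUTSIDE and rbirth[ra] <= rbirth[rb]):
                survivor, dying = ra, rb
            else:
                survivor, dying = rb, ra
            if is_mask[dying]:
                # hole around excluded tissue: persists beyond the sweep.
                # merges at -inf join pre-filtration mask regions and the
                # outside; they are not features.
                if np.isfinite(v):
                    n_mask_holes += 1
                    if include_mask_holes:
                        bars.append(Bar(dim=1, birth=float(v), death=OPEN))
            elif np.isfinite(rbirth[dying]):
                birth = float(v)
                death = float(rbirth[dying])
                if birth > death:
                    bars.append(Bar(dim=1, birth=birth, death=death))
                # birth == death bars are ephemeral (zero persistence): skip
            parent[dying] = survivor
            is_mask[survivor] = is_mask[survivor] or is_mask[dying]

    bars.sort(key=lambda b: (-b.birth, b.death if b.death is not None else -np.inf))
    return bars, n_mask_holes


def barcode(filtration: Filtration, include_mask_holes: bool = False) -> Barcode:
    """Full H0 + H1 barcode of the super-level-set filtration."""
    b0 = h0_barcode(filtration)
    b1, n_mask = _h1_sweep(filtration, include_mask_holes)
    return Barcode(
        bars=b0 + b1,
        grid_shape=filtration.values.shape,  # type: ignore[arg-type]
        connectivity=filtration.connectivity,
        n_mask_holes=n_mask,
    )


# ---------------------------------------------------------------------------
# Barcode statistics
# ---------------------------------------------------------------------------

TOPO_FEATURE_NAMES = (
    "n_bars_dim0",
    "n_bars_dim1",
    "total_persistence_dim0",
    "total_persistence_dim1",
    "max_persistence_dim0",
    "max_persistence_dim1",
    "mean_birth_dim0",
    "mean_birth_dim1",
    "n_hotspots",
    "persistence_entropy_dim0",
    "persistence_entropy_dim1",
)

#: The compact arrangement-only subset used for classification studies:
#: component/hole counts and persistences describe how fibrotic foci are
#: arranged and how well they are separated, and persistences are invariant
#: to a uniform shift of the score level — so these complement, rather than
#: duplicate, the marginal fibrosis features (average score, bin fractions).
#: Mean births and persistence entropies track the overall score level and
#: mostly echo the marginal features.
TOPO_ARRANGEMENT_FEATURES = (
    "n_bars_dim0",
    "n_bars_dim1",
    "n_hotspots",
    "total_persistence_dim0",
    "max_persistence_dim0",
    "total_persistence_dim1",
    "max_persistence_dim1",
)


@dataclass
class TopoFeatureVector:
    n_bars_dim0: int = 0
    n_bars_dim1: int = 0
    total_persistence_dim0: float = 0.0
    total_persistence_dim1: float = 0.0
    max_persistence_dim0: float = 0.0
    max_persistence_dim1: float = 0.0
    mean_birth_dim0: float = 0.0
    mean_birth_dim1: float = 0.0
    n_hotspots: int = 0  # dim-0 bars born at or above the hotspot threshold
    persistence_entropy_dim0: float = 0.0
    persistence_entropy_dim1: float = 0.0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in TOPO_FEATURE_NAMES}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in TOPO_FEATURE_NAMES], dtype=np.float64)


def _persistence_entropy(pers: np.ndarray) -> float:
    total = pers.sum()
    if total <= 0 or pers.size == 0:
        return 0.0
    q = pers / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def barcode_features(
    bc: Barcode,
    hotspot_threshold: float = 0.5,
    death_floor: float | None = None,
    hotspot_min_persistence: float = 0.1,
) -> TopoFeatureVector:
    """Deterministic scalar statistics of a barcode.

    Open bars count toward bar counts, births and the hotspot count; they
    enter the persistence sums only when death_floor (typically the global
    score minimum) is supplied to close them.

    A hotspot is a dimension-0 bar born at or above hotspot_threshold whose
    persistence is at least hotspot_min_persistence — the persistence floor
    is the usual topological denoising step, separating genuine fibrotic
    foci from small fluctuations of the score map.
    """
    out = TopoFeatureVector()
    for d in (0, 1):
        bars = bc.dim(d)
        births = np.array([b.birth for b in bars])
        pers = []
        for b in bars:
            if b.death is not None:
                pers.append(b.birth - b.death)
            elif death_floor is not None:
                pers.append(b.birth - death_floor)
        pers = np.array(pers) if pers else np.empty(0)
        setattr(out, f"n_bars_dim{d}", len(bars))
        setattr(out, f"total_persistence_dim{d}", float(pers.sum()) if pers.size else 0.0)
        setattr(out, f"max_persistence_dim{d}", float(pers.max()) if pers.size else 0.0)
        setattr(out, f"mean_birth_dim{d}", float(births.mean()) if births.size else 0.0)
        setattr(out, f"persistence_entropy_dim{d}", _persistence_entropy(pers))
    out.n_hotspots = sum(
        1
        for b in bc.dim(0)
        if b.birth >= hotspot_threshold and b.persistence >= hotspot_min_persistence
    )
    return out


# ---------------------------------------------------------------------------
# Brute-force oracle (tests only)
# ---------------------------------------------------------------------------

def brute_force_oracle(
    filtration: Filtration, max_cells: int = 1024
) -> list[tuple[float, int, int]]:
    """Per-threshold (t, n_components, n_cycles) by explicit flood fill.

    For every distinct finite value t (descending) the super-level set is
    materialized and labeled with scipy's flood fill: components under the
    foreground connectivity, and cycles as bounded components of the
    4-connected complement (complement regions touching the grid border are
    unbounded and therefore not holes). Guarded to small grids; used only as
    an independent test oracle.
    """
    from scipy import ndimage

    vals = filtration.values
    if vals.size > max_cells:
        raise InvalidArgumentError(
            f"oracle guard: grid has {vals.size} cells > {max_cells}"
        )
    finite = np.isfinite(vals)
    if not finite.any():
        raise DataError("all cells excluded")
    fg_structure = (
        np.ones((3, 3), dtype=int)
        if filtration.connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    bg_structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if filtration.connectivity == 8
        else np.ones((3, 3), dtype=int)
    )
    out = []
    for t in sorted(np.unique(vals[finite]))[::-1]:
        fg = np.where(finite, vals >= t, False)
        _, n_comp = ndimage.label(fg, structure=fg_structure)
        bg = ~fg
        labels, n_bg = ndimage.label(bg, structure=bg_structure)
        border = set(
            np.unique(
                np.concatenate(
                    [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
                )
            )
        )
        n_cycles = len({l for l in range(1, n_bg + 1) if l not in border})
        out.append((float(t), int(n_comp), int(n_cycles)))
    return out


def alive_counts(bars: list[Bar], t: float) -> int:
    """Number of bars alive at threshold t (birth >= t and death below t)."""
    n = 0
    for b in bars:
        if b.birth >= t and (b.death is None or b.death < t):
            n += 1
    return n


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_barcode_csv(bc: Barcode, path, sample_id: str = "") -> None:
    bc.as_dataframe(sample_id).to_csv(path, index=False)


def read_barcode_csv(path) -> Barcode:
    df = pd.read_csv(path)
    bars = []
    for _, row in df.iterrows():
        death = row["death"]
        death = None if (isinstance(death, str) and death == "inf") or (
            isinstance(death, float) and np.isinf(death)
        ) else float(death)
        cell = (
            (int(row["birth_row"]), int(row["birth_col"]))
            if row["birth_row"] >= 0
            else None
        )
        bars.append(Bar(dim=int(row["dim"]), birth=float(row["birth"]), death=death, birth_cell=cell))
    return Barcode(bars=bars, grid_shape=(0, 0))
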