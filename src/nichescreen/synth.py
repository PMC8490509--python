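"""Synthetic coculture plates with exact ground truth.

Emulates the screening assay geometry: each 96-well coculture well seeds
~2,000 CAFs and ~200 cancer cells; the cancer cells grow as round colonies
of mixed Nanog+/Nanog- cells while CAFs scatter across the well.  Four
fields per well are captured at low magnification and montaged 2x2.

The generator renders three 16-bit-scale channels (nuclear / stemness /
fibroblast) as hard-edged disks over a constant background with optional
additive Gaussian noise, and returns a per-cell ground-truth table (class,
position, colony membership), so every scoring step downstream is testable
against exact bookkeeping without a microscope.

Nuclei are hard-edged disks (pixel center inside the radius), not
anti-aliased: the noise-free thresholded mask then equals the rasterized
disk for any sensible offset, which makes pixel-exact recovery of areas and
colony density well defined.  A minimum center-to-center spacing guarantees
nuclei never touch, and colony layouts are re-sampled until the grown,
merged mask forms a single connected component, so the noise-free well is
exactly recoverable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import (
    FieldImage,
    ScoringParams,
    WellPhenotype,
    colony_filter,
    measure_component,
)
from .lda import DilutionGroup

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "EffectModel",
    "PlateData",
    "PlacementError",
    "generate_field",
    "generate_well",
    "generate_plate",
    "expected_phenotype",
    "response_probability",
    "generate_dilution_series",
]

CANCER_POS = "cancer_nanog_pos"
CANCER_NEG = "cancer_nanog_neg"
CAF = "caf"


class PlacementError(ValueError):
    """Requested cells cannot be placed within the spacing constraints."""


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and content of one synthetic well (split over four fields).

    Counts are per *well*; :func:`generate_field` uses them as-is for a
    single field, :func:`generate_well` distributes them over a 2x2 field
    grid.  Defaults mirror the assay seeding densities (2,000 CAFs and 200
    cancer cells per well, ~30% Nanog+ within colonies).
    """

    width_px: int = 600
    height_px: int = 600
    pixel_size_um: float = 1.75
    n_caf: int = 2000
    n_cancer: int = 200
    csc_fraction: float = 0.3
    n_colonies: int = 3
    colony_radius_um: float = 200.0
    nucleus_radius_px: tuple[int, int] = (4, 6)
    background_level: tuple[float, float, float] = (600.0, 400.0, 400.0)
    signal_level: tuple[float, float, float] = (30000.0, 30000.0, 30000.0)
    noise_sd: tuple[float, float, float] = (1500.0, 1500.0, 1500.0)
    seed: int = 0
    # placement constraints; spacing keeps nuclei 8-disconnected
    max_place_tries: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.csc_fraction <= 1.0:
            raise ValueError("csc_fraction must lie in [0, 1]")
        if self.width_px <= 0 or self.height_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("geometric quantities must be strictly positive")
        if self.colony_radius_um <= 0:
            raise ValueError("colony_radius_um must be strictly positive")
        rmin, rmax = self.nucleus_radius_px
        if not (0 < rmin <= rmax):
            raise ValueError("nucleus_radius_px must be a positive (min, max) range")
        if min(self.n_caf, self.n_cancer, self.n_colonies) < 0:
            raise ValueError("counts must be non-negative")
        for tup in (self.background_level, self.signal_level, self.noise_sd):
            if any(v < 0 for v in tup):
                raise ValueError("intensity levels must be non-negative")

    @property
    def min_spacing_px(self) -> float:
        return 2 * self.nucleus_radius_px[1] + 3

    @property
    def colony_radius_px(self) -> float:
        return self.colony_radius_um / self.pixel_size_um


@dataclass
class GroundTruth:
    """Exact bookkeeping for one field or montaged well.

    ``cells`` has one row per placed cell (cell_id, x, y, radius_px, cls,
    colony_id — NaN for cells outside colonies); ``colonies`` one row per
    planted colony.  Classes are mutually exclusive by construction and
    CAFs never carry a colony id.
    """

    cells: pd.DataFrame
    colonies: pd.DataFrame
    shape: tuple[int, int]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if len(self.cells):
            bad = self.cells[(self.cells["cls"] == CAF) & self.cells["colony_id"].notna()]
            if len(bad):
                raise ValueError("CAFs must not carry a colony_id")
        referenced = set(self.cells["colony_id"].dropna().astype(int))
        listed = set(self.colonies["colony_id"].astype(int)) if len(self.colonies) else set()
        if listed - referenced:
            raise ValueError("every colony must be referenced by >= 1 cell")

    def class_counts(self) -> dict[str, int]:
        counts = {CANCER_POS: 0, CANCER_NEG: 0, CAF: 0}
        counts.update(self.cells["cls"].value_counts().to_dict())
        return counts


@dataclass(frozen=True)
class EffectModel:
    """Multiplicative per-compound effects applied before synthesis.

    1.0 means no change.  Effects scale the planted csc fraction, colony
    count, cancer-cell survival and CAF survival; well counts are the
    rounded scaled values, optionally jittered by a lognormal well-to-well
    CV (default 0: counts are exact bookkeeping).
    """

    csc_fraction: float = 1.0
    colony_count: float = 1.0
    cancer_survival: float = 1.0
    caf_survival: float = 1.0
    replicates: int = 3
    dose: float = 1.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("csc_fraction", "colony_count", "cancer_survival", "caf_survival"):
            if getattr(self, name) < 0:
                raise ValueError(f"effect {name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# placement helpers

class _SpacedSampler:
    """Dart-throwing with a minimum pairwise distance via a uniform grid."""

    def __init__(self, min_dist: float) -> None:
        self.min_dist = float(min_dist)
        self.cell = max(self.min_dist, 1.0)
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x: float, y: float) -> bool:
        kx, ky = self._key(x, y)
        d2 = self.min_dist * self.min_dist
        for i in range(kx - 1, kx + 2):
            for j in range(ky - 1, ky + 2):
                for px, py in self.grid.get((i, j), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < d2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.grid.setdefault(self._key(x, y), []).append((x, y))


def _rasterize_disks(xs, ys, radii, shape) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    h, w = shape
    for x, y, r in zip(xs, ys, radii):
        r = int(r)
        x0, y0 = int(round(x)), int(round(y))
        ylo, yhi = max(0, y0 - r), min(h, y0 + r + 1)
        xlo, xhi = max(0, x0 - r), min(w, x0 + r + 1)
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        canvas[ylo:yhi, xlo:xhi] |= (yy - y) ** 2 + (xx - x) ** 2 <= r * r
    return canvas


def _disk_selem(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def _sample_colony(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius_px: float,
    n_cells: int,
    spec: FieldSpec,
    sampler: _SpacedSampler,
    grow_px: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place n_cells as a jittered hexagonal packing around the center.

    The lattice pitch sits between the minimum nucleus spacing and the
    grow-merge distance, so nuclei stay disconnected in the nuclear channel
    while their grown objects always merge into one component; the n lattice
    sites closest to the center give a round, convex colony.  Centers snap
    to the pixel grid so nucleus masks are symmetric digital disks.
    """
    rmin, rmax = spec.nucleus_radius_px
    inner = radius_px - rmax
    if inner <= 0:
        raise PlacementError("colony radius smaller than a nucleus")
    pitch = spec.min_spacing_px + 1
    # worst-case neighbor distance after +-1 px jitter must stay within the
    # digital merge distance of two grown minimal nuclei
    if pitch + 2 > 2 * (rmin + grow_px):
        raise PlacementError("grow radius too small to connect spaced nuclei")
    # hex lattice covering the colony disk
    rows = int(inner / (pitch * math.sqrt(3) / 2)) + 2
    cols = int(inner / pitch) + 2
    pts = []
    for j in range(-rows, rows + 1):
        for i in range(-cols, cols + 1):
            x = center[0] + (i + 0.5 * (j % 2)) * pitch
            y = center[1] + j * (pitch * math.sqrt(3) / 2)
            d = math.hypot(x - center[0], y - center[1])
            if d <= inner:
                pts.append((d, x, y))
    if len(pts) < n_cells:
        raise PlacementError(
            f"colony of {n_cells} cells does not fit within radius "
            f"{radius_px:.0f} px at spacing {spec.min_spacing_px:.0f} px"
        )
    pts = [pts[k] for k in rng.permutation(len(pts))]
    pts.sort(key=lambda t: t[0])  # stable sort: ties stay shuffled
    pts = pts[:n_cells]
    xs, ys = [], []
    for _, x, y in pts:
        # jitter one axis only: keeps worst-case neighbor distance within
        # the merge limit and the minimum distance above the spacing floor
        xj = float(round(x) + rng.integers(-1, 2))
        yj = float(round(y))
        xs.append(xj)
        ys.append(yj)
    for x, y in zip(xs, ys):
        sampler.add(x, y)
    radii = rng.integers(rmin, rmax + 1, size=n_cells)
    return np.asarray(xs), np.asarray(ys), radii


def _scatter(
    rng: np.random.Generator,
    n: int,
    spec: FieldSpec,
    sampler: _SpacedSampler,
    margin: float,
    keep_out: list[tuple[float, float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions avoiding keep-out disks and the global spacing."""
    xs, ys = [], []
    for _ in range(n):
        for _try in range(spec.max_place_tries * 10):
            x = float(round(rng.uniform(margin, spec.width_px - margin)))
            y = float(round(rng.uniform(margin, spec.height_px - margin)))
            if any((x - cx) ** 2 + (y - cy) ** 2 < kr * kr for cx, cy, kr in keep_out):
                continue
            if sampler.ok(x, y):
                sampler.add(x, y)
                xs.append(x)
                ys.append(y)
                break
        else:
            raise PlacementError(
                f"could not place {n} scattered cells without overlap"
            )
    return np.asarray(xs), np.asarray(ys)


def _render(spec: FieldSpec, cells: pd.DataFrame, rng: np.random.Generator,
            field_index: int = 0) -> FieldImage:
    shape = (spec.height_px, spec.width_px)
    channels = []
    masks = {
        0: cells,  # nuclear: every cell
        1: cells[cells["cls"] == CANCER_POS],  # stemness over Nanog+ nuclei
        2: cells[cells["cls"] == CAF],  # fibroblast over CAF nuclei
    }
    for ch in range(3):
        img = np.full(shape, spec.background_level[ch], dtype=np.float64)
        sub = masks[ch]
        if len(sub):
            disk = _rasterize_disks(
                sub["x"].to_numpy(), sub["y"].to_numpy(),
                sub["radius_px"].to_numpy(), shape,
            )
            img[disk] = spec.signal_level[ch]
        if spec.noise_sd[ch] > 0:
            img += rng.normal(0.0, spec.noise_sd[ch], size=shape)
            np.clip(img, 0.0, None, out=img)
        channels.append(img)
    return FieldImage(channels[0], channels[1], channels[2],
                      pixel_size_um=spec.pixel_size_um, field_index=field_index)


def _split_even(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _synthesize_field(
    spec: FieldSpec,
    rng: np.random.Generator,
    colony_sizes: list[int],
    colony_pos: list[int],
    n_scatter_cancer: int = 0,
    n_scatter_pos: int = 0,
    field_index: int = 0,
    colony_id_start: int = 0,
    cell_id_start: int = 0,
) -> tuple[FieldImage, pd.DataFrame, pd.DataFrame]:
    """Place and render one field with explicit per-colony compositions."""
    rmin, rmax = spec.nucleus_radius_px
    cr = spec.colony_radius_px
    margin = rmax + 8
    sampler = _SpacedSampler(spec.min_spacing_px)

    # colony centers: inside the field, non-overlapping grown masks
    centers: list[tuple[float, float]] = []
    cmargin = cr + margin
    if colony_sizes and (2 * cmargin >= spec.width_px or 2 * cmargin >= spec.height_px):
        raise PlacementError("colony does not fit in the field")
    min_cd = 2 * cr + 2 * (rmax + 5) + 6
    if colony_sizes:
        lo_x, hi_x = cmargin, spec.width_px - cmargin
        lo_y, hi_y = cmargin, spec.height_px - cmargin
        k = len(colony_sizes)
        for _try in range(spec.max_place_tries):
            cand = [(rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)) for _ in range(k)]
            if all(
                (cand[i][0] - cand[j][0]) ** 2 + (cand[i][1] - cand[j][1]) ** 2
                >= min_cd**2
                for i in range(k) for j in range(i + 1, k)
            ):
                centers = cand
                break
        else:
            # tight fits: deterministic corner/edge layout with maximal spread
            pattern = [(lo_x, lo_y), (hi_x, hi_y), (lo_x, hi_y), (hi_x, lo_y),
                       ((lo_x + hi_x) / 2, lo_y), ((lo_x + hi_x) / 2, hi_y)]
            if k > len(pattern):
                raise PlacementError("could not place non-overlapping colonies")
            cand = pattern[:k]
            if any(
                (cand[i][0] - cand[j][0]) ** 2 + (cand[i][1] - cand[j][1]) ** 2
                < min_cd**2
                for i in range(k) for j in range(i + 1, k)
            ):
                raise PlacementError("could not place non-overlapping colonies")
            centers = cand

    rows: list[dict] = []
    col_rows: list[dict] = []
    cid = colony_id_start
    for (cx, cy), size, n_pos in zip(centers, colony_sizes, colony_pos):
        xs, ys, radii = _sample_colony(rng, (cx, cy), cr, size, spec, sampler)
        pos_idx = set(rng.choice(size, size=n_pos, replace=False).tolist()) if n_pos else set()
        for i in range(size):
            rows.append({
                "x": xs[i], "y": ys[i], "radius_px": int(radii[i]),
                "cls": CANCER_POS if i in pos_idx else CANCER_NEG,
                "colony_id": cid,
            })
        col_rows.append({
            "colony_id": cid, "center_x": cx, "center_y": cy,
            "radius_px": cr, "n_cells": size, "n_nanog_pos": n_pos,
        })
        cid += 1

    keep_out = [(cx, cy, cr + spec.min_spacing_px) for cx, cy in centers]
    if n_scatter_cancer:
        xs, ys = _scatter(rng, n_scatter_cancer, spec, sampler, margin, keep_out)
        radii = rng.integers(rmin, rmax + 1, size=n_scatter_cancer)
        pos_idx = set(
            rng.choice(n_scatter_cancer, size=n_scatter_pos, replace=False).tolist()
        ) if n_scatter_pos else set()
        for i in range(n_scatter_cancer):
            rows.append({
                "x": xs[i], "y": ys[i], "radius_px": int(radii[i]),
                "cls": CANCER_POS if i in pos_idx else CANCER_NEG,
                "colony_id": np.nan,
            })
    if spec.n_caf:
        xs, ys = _scatter(rng, spec.n_caf, spec, sampler, margin, keep_out)
        radii = rng.integers(rmin, rmax + 1, size=spec.n_caf)
        for i in range(spec.n_caf):
            rows.append({
                "x": xs[i], "y": ys[i], "radius_px": int(radii[i]),
                "cls": CAF, "colony_id": np.nan,
            })

    cells = pd.DataFrame(
        rows, columns=["x", "y", "radius_px", "cls", "colony_id"]
    )
    cells.insert(0, "cell_id", np.arange(cell_id_start, cell_id_start + len(cells)))
    colonies = pd.DataFrame(
        col_rows,
        columns=["colony_id", "center_x", "center_y", "radius_px", "n_cells", "n_nanog_pos"],
    )
    image = _render(spec, cells, rng, field_index=field_index)
    return image, cells, colonies


def generate_field(spec: FieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Generate one field image with ground truth.

    All ``spec`` counts land in this single field; cancer cells fill the
    requested colonies (split as evenly as possible), or scatter as
    singletons when ``n_colonies == 0``.  The Nanog+ count is exactly
    ``round(csc_fraction * n_cancer)``.  Identical seeds give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos_total = int(round(spec.csc_fraction * spec.n_cancer))
    if spec.n_colonies > 0 and spec.n_cancer > 0:
        sizes = _split_even(spec.n_cancer, spec.n_colonies)
        pos = _allocate_positives(rng, sizes, n_pos_total)
        img, cells, cols = _synthesize_field(spec, rng, sizes, pos)
    else:
        img, cells, cols = _synthesize_field(
            spec, rng, [], [], n_scatter_cancer=spec.n_cancer,
            n_scatter_pos=n_pos_total,
        )
    return img, GroundTruth(cells, cols, (spec.height_px, spec.width_px),
                            spec.pixel_size_um)


def _allocate_positives(rng: np.random.Generator, sizes: list[int], n_pos: int) -> list[int]:
    """Distribute the exact Nanog+ total over colonies (weighted without
    replacement, like drawing the positive cells uniformly)."""
    total = sum(sizes)
    n_pos = min(n_pos, total)
    picks = rng.choice(total, size=n_pos, replace=False)
    bounds = np.cumsum([0] + sizes)
    return [int(((picks >= bounds[i]) & (picks < bounds[i + 1])).sum())
            for i in range(len(sizes))]


def generate_well(
    spec: FieldSpec, well_id: str = "well", render: bool = True
) -> tuple[list[FieldImage] | None, GroundTruth]:
    """Generate the four fields of one well; truth in montage coordinates.

    The per-well counts are split across a 2x2 field grid: colonies
    round-robin over fields, CAFs evenly.  Ground-truth coordinates refer
    to the montage frame (field i at offset (i//2*H, i%2*W)).  With
    ``render=False`` only the ground truth is produced (fast path for
    screen-scale plates).
    """
    rng = np.random.default_rng(spec.seed)
    n_fields = 4
    n_pos_total = int(round(spec.csc_fraction * spec.n_cancer))

    if spec.n_colonies > 0 and spec.n_cancer > 0:
        sizes = _split_even(spec.n_cancer, spec.n_colonies)
        pos = _allocate_positives(rng, sizes, n_pos_total)
        per_field: list[list[int]] = [[] for _ in range(n_fields)]
        per_field_pos: list[list[int]] = [[] for _ in range(n_fields)]
        for j, (s, p) in enumerate(zip(sizes, pos)):
            per_field[j % n_fields].append(s)
            per_field_pos[j % n_fields].append(p)
        scatter = [0] * n_fields
        scatter_pos = [0] * n_fields
    else:
        per_field = [[] for _ in range(n_fields)]
        per_field_pos = [[] for _ in range(n_fields)]
        scatter = _split_even(spec.n_cancer, n_fields)
        scatter_pos = _allocate_positives(rng, scatter, n_pos_total) if spec.n_cancer else [0] * n_fields
    cafs = _split_even(spec.n_caf, n_fields)

    fields: list[FieldImage] = []
    cell_frames: list[pd.DataFrame] = []
    col_frames: list[pd.DataFrame] = []
    cid = 0
    cell_id = 0
    h, w = spec.height_px, spec.width_px
    for i in range(n_fields):
        fspec = replace(spec, n_caf=cafs[i], n_cancer=0, n_colonies=0)
        img, cells, cols = _synthesize_field(
            fspec, rng, per_field[i], per_field_pos[i],
            n_scatter_cancer=scatter[i], n_scatter_pos=scatter_pos[i],
            field_index=i, colony_id_start=cid, cell_id_start=cell_id,
        )
        if not render:
            img = None
        y0, x0 = (i // 2) * h, (i % 2) * w
        cells = cells.copy()
        cells["x"] += x0
        cells["y"] += y0
        if len(cols):
            cols = cols.copy()
            cols["center_x"] += x0
            cols["center_y"] += y0
        cid += len(cols)
        cell_id += len(cells)
        if render:
            fields.append(img)
        cell_frames.append(cells)
        col_frames.append(cols)
    cells = pd.concat(cell_frames, ignore_index=True)
    colonies = pd.concat([c for c in col_frames if len(c)], ignore_index=True) \
        if any(len(c) for c in col_frames) else col_frames[0]
    truth = GroundTruth(cells, colonies, (2 * h, 2 * w), spec.pixel_size_um)
    return (fields if render else None), truth


# ---------------------------------------------------------------------------
# truth-side phenotype oracle

def expected_phenotype(
    truth: GroundTruth, params: ScoringParams | None = None
) -> WellPhenotype:
    """The six parameters implied by ground truth alone.

    Counts come straight from the table; colony areas and form factors are
    computed by rasterizing the known nucleus disks, growing, merging and
    filling exactly as the scoring pipeline defines a colony mask — from
    coordinates, not from the image.  A colony passes the stemness-SD
    filter when it contains at least one Nanog+ cell (its mask then spans
    bright and dark pixels); an all-negative colony passes only in the
    noise-free auto-threshold case where the minimum SD is 0.
    """
    params = params or ScoringParams()
    cells = truth.cells
    total_cells = len(cells)
    total_cafs = int((cells["cls"] == CAF).sum())
    px2 = truth.pixel_size_um ** 2

    total_cscs = 0
    colony_count = 0
    total_colony_cells = 0
    total_area = 0.0
    for _, col in truth.colonies.iterrows():
        members = cells[cells["colony_id"] == col["colony_id"]]
        pad = int(max(members["radius_px"])) + params.grow_px + 2
        x0 = int(math.floor(members["x"].min())) - pad
        y0 = int(math.floor(members["y"].min())) - pad
        w = int(math.ceil(members["x"].max())) - x0 + pad + 1
        h = int(math.ceil(members["y"].max())) - y0 + pad + 1
        mask = _rasterize_disks(
            members["x"].to_numpy() - x0, members["y"].to_numpy() - y0,
            members["radius_px"].to_numpy(), (h, w),
        )
        mask = ndimage.binary_dilation(mask, structure=_disk_selem(params.grow_px))
        mask = ndimage.binary_fill_holes(mask)
        area_um2, ff = measure_component(mask, truth.pixel_size_um)
        n_pos = int((members["cls"] == CANCER_POS).sum())
        # SD filter proxy: a colony with Nanog+ members always clears the
        # marker-variability filter (bright disks over dark gaps); an
        # all-negative colony clears it only when the minimum SD is 0
        sd_pass = n_pos > 0 or params.min_stemness_sd == 0
        if sd_pass and colony_filter(area_um2, ff, math.inf, params, min_sd=0.0):
            colony_count += 1
            total_cscs += n_pos
            total_colony_cells += int(len(members))
            total_area += area_um2
    if colony_count == 0:
        return WellPhenotype(total_cells, total_cafs, 0, 0, 0, 0.0, no_colonies=True)
    return WellPhenotype(
        total_cells, total_cafs, total_cscs, colony_count, total_colony_cells,
        total_colony_cells / total_area,
    )


# ---------------------------------------------------------------------------
# plate-level generation

@dataclass
class PlateData:
    """A generated plate: annotation, per-well truth, phenotypes, images."""

    annotation: pd.DataFrame
    truths: dict[str, GroundTruth]
    phenotypes: pd.DataFrame
    images: dict[str, list[FieldImage]] | None = None


def _well_name(i: int) -> str:
    plate, k = divmod(i, 96)
    name = f"{chr(65 + k // 12)}{k % 12 + 1:02d}"
    return name if plate == 0 else f"P{plate + 1}-{name}"


def _scaled_spec(base: FieldSpec, eff: EffectModel, rng: np.random.Generator,
                 seed: int) -> FieldSpec:
    def jitter() -> float:
        return math.exp(rng.normal(0.0, eff.noise_cv)) if eff.noise_cv > 0 else 1.0

    n_colonies = int(round(eff.colony_count * base.n_colonies * jitter()))
    n_cancer = int(round(eff.cancer_survival * base.n_cancer * jitter()))
    if n_colonies == 0:
        n_cancer = 0  # colony-resident cancer cells die with their colonies
    return replace(
        base,
        n_caf=int(round(eff.caf_survival * base.n_caf * jitter())),
        n_cancer=n_cancer,
        n_colonies=n_colonies,
        csc_fraction=min(1.0, base.csc_fraction * eff.csc_fraction * jitter()),
        seed=seed,
    )


def generate_plate(
    effects: dict[str, EffectModel],
    base: FieldSpec | None = None,
    n_control_wells: int = 3,
    render: bool = False,
    params: ScoringParams | None = None,
    seed: int | None = None,
) -> PlateData:
    """Generate a plate of wells with planted per-compound effects.

    Controls (effects all 1.0) occupy the first ``n_control_wells`` wells;
    each compound then gets ``replicates`` wells whose ground truth reflects
    its effects.  Phenotypes are derived from ground truth (and are what a
    perfect scorer would measure); with ``render=True`` the field images are
    kept as well.
    """
    base = base or FieldSpec()
    if n_control_wells < 1:
        raise ValueError("a plate needs at least one control well")
    if not effects and n_control_wells < 1:
        raise ValueError("empty plate")
    if len(set(effects)) != len(effects):  # dict keys are unique; guard for lists
        raise ValueError("duplicate compound ids")
    rng = np.random.default_rng(base.seed if seed is None else seed)

    layout: list[tuple[str, str, int, str, EffectModel]] = []
    control = EffectModel()
    for r in range(n_control_wells):
        layout.append(("control", "control", r + 1, "control", control))
    for comp, eff in effects.items():
        for r in range(eff.replicates):
            layout.append((comp, comp, r + 1, "treated", eff))

    ann_rows = []
    truths: dict[str, GroundTruth] = {}
    pheno_rows = []
    images: dict[str, list[FieldImage]] = {}
    for i, (comp, _, rep, role, eff) in enumerate(layout):
        well = _well_name(i)
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec_i = _scaled_spec(base, eff, rng, child_seed)
        fields, truth = generate_well(spec_i, well_id=well, render=render)
        truths[well] = truth
        if render:
            images[well] = fields
        ann_rows.append({
            "well": well, "compound": comp, "dose": eff.dose,
            "replicate": rep, "role": role,
        })
        ph = expected_phenotype(truth, params)
        pheno_rows.append({"well": well, **ph.as_dict()})
    annotation = pd.DataFrame(ann_rows)
    phenotypes = pd.DataFrame(pheno_rows)
    return PlateData(annotation, truths, phenotypes, images if render else None)


# ---------------------------------------------------------------------------
# limiting-dilution tables

def response_probability(frequency: float, dose: float) -> float:
    """Single-hit response probability 1 - exp(-f * dose); dose 0 -> 0."""
    if not 0.0 < frequency <= 1.0:
        raise ValueError("frequency must lie in (0, 1]")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return -math.expm1(-frequency * dose)


def generate_dilution_series(
    true_frequency: float,
    doses: list[int],
    wells_per_dose: int,
    seed: int = 0,
    label: str = "group",
) -> DilutionGroup:
    """Simulate a limiting-dilution design under the single-hit model.

    Each of ``wells_per_dose`` wells at dose d responds independently with
    probability 1 - exp(-f d).
    """
    if not 0.0 < true_frequency <= 1.0:
        raise ValueError("true_frequency must lie in (0, 1]")
    if wells_per_dose < 1:
        raise ValueError("wells_per_dose must be >= 1")
    doses = [int(d) for d in doses]
    if any(d < 1 for d in doses):
        raise ValueError("doses must be positive integers")
    rng = np.random.default_rng(seed)
    responding = [
        int(rng.binomial(wells_per_dose, response_probability(true_frequency, d)))
        for d in doses
    ]
    return DilutionGroup(
        dose=np.asarray(doses),
        tested=np.full(len(doses), wells_per_dose, dtype=int),
        responding=np.asarray(responding),
        label=label,
    )
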