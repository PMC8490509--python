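"""Scoring of three-channel coculture well images into six phenotypic parameters.

The assay images a 96-well coculture of cancer cells and cancer-associated
fibroblasts (CAFs) in three fluorescence channels: a nuclear stain (Hoechst
33342), a stemness marker (Nanog) and a fibroblast marker (CD90).  Four
fields per well are montaged, nuclei are detected on the nuclear channel,
per-cell marker positivity is called by an intensity-above-local-threshold
rule, and colonies are built by growing the cancer-cell nuclei, merging
touching objects, filling holes, and filtering on shape (elliptical form
factor <= 2.5), size (area > 10,000 um^2) and Nanog intensity variability.

Six parameters summarise a well:

* total cells        — Hoechst+ nuclei
* total CAFs         — CD90+ cells
* total CSCs         — Nanog+ cells inside colonies
* colony count       — colonies passing all three filters
* total colony cells — all cells inside colonies
* colony density     — total colony cells / total colony area (cells/um^2)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .morphology import open_filter, top_hat

__all__ = [
    "FieldImage",
    "WellMontage",
    "ScoringParams",
    "CellRecord",
    "ColonyRecord",
    "WellPhenotype",
    "montage_fields",
    "detect_cells",
    "identify_colonies",
    "colony_filter",
    "compute_phenotype",
    "score_well",
]

log = logging.getLogger(__name__)

CHANNELS = ("nuclear", "stemness", "fibroblast")


@dataclass(frozen=True)
class FieldImage:
    """One microscope field: three equally shaped non-negative rasters."""

    nuclear: np.ndarray
    stemness: np.ndarray
    fibroblast: np.ndarray
    pixel_size_um: float
    field_index: int = 0

    def __post_init__(self) -> None:
        shape = self.nuclear.shape
        if self.stemness.shape != shape or self.fibroblast.shape != shape:
            raise ValueError("channel rasters must share one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape


@dataclass(frozen=True)
class WellMontage:
    """2x2 grid stitch of up to four fields of one well.

    ``field_origins`` maps field_index -> (y0, x0) pixel offset of that field
    in the montage, so field coordinates are recoverable.
    """

    nuclear: np.ndarray
    stemness: np.ndarray
    fibroblast: np.ndarray
    pixel_size_um: float
    well_id: str = "well"
    field_origins: dict[int, tuple[int, int]] = field(default_factory=dict)
    field_shape: tuple[int, int] = (0, 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class ScoringParams:
    """Tunable parameters of the scoring pipeline.

    The filter geometry (top-hat 30 px, open 6 px, grow 5 px) and the colony
    thresholds (area > 10,000 um^2, form factor <= 2.5) are the published
    values; widths, intensity offsets and the minimum Nanog SD are the
    user-defined knobs of the original cell-scoring module and default to
    values suited to 16-bit images with signal ~30,000 counts over background.
    """

    top_hat_size_px: int = 30
    open_size_px: int = 6
    nucleus_width_min_px: float = 4.0
    nucleus_width_max_px: float = 20.0
    # intensity-above-local-threshold offsets, per channel, in counts
    nuclear_offset: float = 6000.0
    stemness_offset: float = 10000.0
    fibroblast_offset: float = 6000.0
    grow_px: int = 5
    colony_min_area_um2: float = 10_000.0
    max_form_factor: float = 2.5
    # None -> 2x the background SD of the filtered stemness channel
    min_stemness_sd: float | None = None
    # simple threshold separating feature from background for QC/flat checks
    simple_threshold: float = 5000.0

    def __post_init__(self) -> None:
        if self.top_hat_size_px <= 0 or self.open_size_px <= 0 or self.grow_px <= 0:
            raise ValueError("element sizes must be positive")
        if not (0 < self.nucleus_width_min_px < self.nucleus_width_max_px):
            raise ValueError("need 0 < min width < max width")

    @property
    def local_window_px(self) -> int:
        """Local-background window: 4x the maximum nucleus width, odd."""
        w = int(round(4 * self.nucleus_width_max_px))
        return w + 1 - w % 2


@dataclass
class CellRecord:
    """One detected nucleus with per-channel means and positivity calls."""

    cell_id: int
    centroid_x: float
    centroid_y: float
    label: int
    area_px: int
    equivalent_width_px: float
    mean_nuclear: float
    mean_stemness: float
    mean_fibroblast: float
    nanog_pos: bool
    cd90_pos: bool
    pixels: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class ColonyRecord:
    """A filtered colony: filled connected cluster of grown cancer cells."""

    colony_id: int
    member_cell_ids: list[int]
    area_px: int
    area_um2: float
    form_factor: float
    nanog_pos_count: int
    nanog_neg_count: int
    stemness_intensity_sd: float
    centroid_x: float
    centroid_y: float
    pixels: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def member_count(self) -> int:
        return self.nanog_pos_count + self.nanog_neg_count


@dataclass(frozen=True)
class WellPhenotype:
    """The six per-well parameters (plus an explicit no-colony flag)."""

    total_cells: int
    total_cafs: int
    total_cscs: int
    colony_count: int
    total_colony_cells: int
    colony_density: float
    no_colonies: bool = False

    PARAMETERS = (
        "total_cells",
        "total_cafs",
        "total_cscs",
        "colony_count",
        "total_colony_cells",
        "colony_density",
    )

    def as_dict(self) -> dict[str, float]:
        d = {p: getattr(self, p) for p in self.PARAMETERS}
        d["no_colonies"] = self.no_colonies
        return d


_GRID = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}


def montage_fields(fields: list[FieldImage], well_id: str = "well") -> WellMontage:
    """Stitch 1-4 fields into a deterministic 2x2 montage.

    Field ``field_index`` i lands at grid position (i // 2, i % 2); absent
    positions are zero-filled.  Shapes and pixel sizes must agree.
    """
    if not 1 <= len(fields) <= 4:
        raise ValueError("expected 1-4 fields")
    shape = fields[0].shape
    px = fields[0].pixel_size_um
    for f in fields:
        if f.shape != shape:
            raise ValueError("fields must share one shape")
        if f.pixel_size_um != px:
            raise ValueError("fields must share one pixel size")
    if len(fields) == 1:
        f = fields[0]
        return WellMontage(
            f.nuclear.copy(), f.stemness.copy(), f.fibroblast.copy(), px,
            well_id=well_id, field_origins={f.field_index: (0, 0)}, field_shape=shape,
        )
    h, w = shape
    canvas = {c: np.zeros((2 * h, 2 * w), dtype=np.float64) for c in CHANNELS}
    origins: dict[int, tuple[int, int]] = {}
    for f in fields:
        if f.field_index not in _GRID:
            raise ValueError(f"field_index must be 0-3, got {f.field_index}")
        if f.field_index in origins:
            raise ValueError(f"duplicate field_index {f.field_index}")
        gy, gx = _GRID[f.field_index]
        y0, x0 = gy * h, gx * w
        origins[f.field_index] = (y0, x0)
        for c in CHANNELS:
            canvas[c][y0 : y0 + h, x0 : x0 + w] = getattr(f, c)
    return WellMontage(
        canvas["nuclear"], canvas["stemness"], canvas["fibroblast"], px,
        well_id=well_id, field_origins=origins, field_shape=shape,
    )


def _local_mean(image: np.ndarray, window: int) -> np.ndarray:
    return ndimage.uniform_filter(np.asarray(image, dtype=np.float64), size=window,
                                  mode="reflect")


def preprocess_stemness(montage: WellMontage, params: ScoringParams) -> np.ndarray:
    """Top-hat then open filter on the stemness channel (pipeline order)."""
    return open_filter(top_hat(montage.stemness, params.top_hat_size_px),
                       params.open_size_px)


def detect_cells(
    montage: WellMontage,
    params: ScoringParams | None = None,
    stemness_filtered: np.ndarray | None = None,
) -> list[CellRecord]:
    """Detect nuclei and call Nanog/CD90 positivity per cell.

    A nucleus is a connected component of nuclear-channel pixels above the
    local background (large-window mean) plus ``nuclear_offset`` whose
    equivalent width (diameter of the equal-area circle) lies strictly
    inside the configured (min, max) range.  Marker positivity requires the
    mean marker intensity over the nucleus footprint to exceed the marker's
    local background plus its offset; the stemness channel is measured after
    top-hat + open filtering.
    """
    params = params or ScoringParams()
    nuc = np.asarray(montage.nuclear, dtype=np.float64)
    if nuc.size == 0:
        raise ValueError("empty montage")
    for c in CHANNELS:
        if not np.all(np.isfinite(montage.channel(c))):
            raise ValueError(f"non-finite pixels in {c} channel")
    if stemness_filtered is None:
        stemness_filtered = preprocess_stemness(montage, params)
    fib = np.asarray(montage.fibroblast, dtype=np.float64)

    win = params.local_window_px
    thr = _local_mean(nuc, win) + params.nuclear_offset
    stem_thr = _local_mean(stemness_filtered, win) + params.stemness_offset
    fib_thr = _local_mean(fib, win) + params.fibroblast_offset

    mask = nuc > thr
    labels, n_labels = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        return []

    records: list[CellRecord] = []
    objects = ndimage.find_objects(labels)
    cell_id = 0
    collisions = 0
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        sub = labels[slc] == lab
        area = int(sub.sum())
        width = 2.0 * math.sqrt(area / math.pi)
        if not (params.nucleus_width_min_px < width < params.nucleus_width_max_px):
            continue
        ys, xs = np.nonzero(sub)
        ys = ys + slc[0].start
        xs = xs + slc[1].start
        mean_nuc = float(nuc[ys, xs].mean())
        mean_stem = float(stemness_filtered[ys, xs].mean())
        mean_fib = float(fib[ys, xs].mean())
        nanog = mean_stem > float(stem_thr[ys, xs].mean())
        cd90 = mean_fib > float(fib_thr[ys, xs].mean())
        if nanog and cd90:
            collisions += 1
        records.append(
            CellRecord(
                cell_id=cell_id,
                centroid_x=float(xs.mean()),
                centroid_y=float(ys.mean()),
                label=lab,
                area_px=area,
                equivalent_width_px=width,
                mean_nuclear=mean_nuc,
                mean_stemness=mean_stem,
                mean_fibroblast=mean_fib,
                nanog_pos=bool(nanog),
                cd90_pos=bool(cd90),
                pixels=(ys, xs),
            )
        )
        cell_id += 1
    if collisions:
        # CD90+ wins: such cells count as CAFs and never enter colonies
        log.warning("%d cell(s) both CD90+ and Nanog+; treated as CAFs", collisions)
    return records


def colony_filter(area_um2: float, form_factor: float, stemness_sd: float,
                  params: ScoringParams, min_sd: float | None = None) -> bool:
    """The three published colony filters, applied exactly at the thresholds.

    Keep a candidate iff area > 10,000 um^2 (strict), form factor <= 2.5,
    and stemness SD >= the minimum SD (user-defined; default derived from
    background noise by the caller).
    """
    if min_sd is None:
        min_sd = params.min_stemness_sd if params.min_stemness_sd is not None else 0.0
    return (
        area_um2 > params.colony_min_area_um2
        and form_factor <= params.max_form_factor
        and stemness_sd >= min_sd
    )


def measure_component(mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Area (um^2) and elliptical form factor of one filled binary component.

    The form factor is the major/minor axis ratio of the second-moment
    (inertia-equivalent) ellipse of the mask; 1 for a circle.
    """
    area_um2 = float(mask.sum()) * pixel_size_um**2
    props = regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    ff = props.axis_major_length / minor if minor > 0 else math.inf
    return area_um2, ff


def grow_and_label(
    cells: list[CellRecord], shape: tuple[int, int], grow_px: int
) -> tuple[np.ndarray, int]:
    """Dilate the given nuclei by a disk and label touching grown objects."""
    canvas = np.zeros(shape, dtype=bool)
    for c in cells:
        if c.pixels is None:
            raise ValueError("cell records lack pixel footprints")
        canvas[c.pixels] = True
    if grow_px > 0:
        yy, xx = np.mgrid[-grow_px : grow_px + 1, -grow_px : grow_px + 1]
        selem = (yy * yy + xx * xx) <= grow_px * grow_px
        canvas = ndimage.binary_dilation(canvas, structure=selem)
    return ndimage.label(canvas, structure=np.ones((3, 3), dtype=int))


def identify_colonies(
    cells: list[CellRecord],
    montage: WellMontage,
    params: ScoringParams | None = None,
    stemness_filtered: np.ndarray | None = None,
) -> list[ColonyRecord]:
    """Build colonies from non-CD90+ cells and apply the three filters.

    Candidate nuclei are dilated by the grow radius, touching objects merge
    into 8-connected components, holes are filled per component, and each
    filled component is kept iff it passes the area, form-factor and
    stemness-SD filters.  Cancer cells only: CD90+ cells never seed colonies.
    """
    params = params or ScoringParams()
    if stemness_filtered is None:
        stemness_filtered = preprocess_stemness(montage, params)
    candidates = [c for c in cells if not c.cd90_pos]
    if not candidates:
        return []
    labels, n_labels = grow_and_label(candidates, montage.shape, params.grow_px)
    if n_labels == 0:
        return []

    if params.min_stemness_sd is not None:
        min_sd = params.min_stemness_sd
    else:
        bg = stemness_filtered[labels == 0]
        min_sd = 2.0 * float(bg.std()) if bg.size else 0.0

    # cell -> grown component via the nucleus centroid pixel
    members: dict[int, list[CellRecord]] = {}
    for c in candidates:
        lab = int(labels[int(round(c.centroid_y)), int(round(c.centroid_x))])
        members.setdefault(lab, []).append(c)

    px2 = montage.pixel_size_um ** 2
    colonies: list[ColonyRecord] = []
    next_id = 0
    for lab, slc in enumerate(ndimage.find_objects(labels), start=1):
        if slc is None:
            continue
        comp = ndimage.binary_fill_holes(labels[slc] == lab)
        area_px = int(comp.sum())
        area_um2, ff = measure_component(comp, montage.pixel_size_um)
        ys, xs = np.nonzero(comp)
        ys = ys + slc[0].start
        xs = xs + slc[1].start
        sd = float(stemness_filtered[ys, xs].std())
        if not colony_filter(area_um2, ff, sd, params, min_sd=min_sd):
            continue
        cell_list = members.get(lab, [])
        n_pos = sum(1 for c in cell_list if c.nanog_pos)
        colonies.append(
            ColonyRecord(
                colony_id=next_id,
                member_cell_ids=[c.cell_id for c in cell_list],
                area_px=area_px,
                area_um2=area_um2,
                form_factor=ff,
                nanog_pos_count=n_pos,
                nanog_neg_count=len(cell_list) - n_pos,
                stemness_intensity_sd=sd,
                centroid_x=float(xs.mean()),
                centroid_y=float(ys.mean()),
                pixels=(ys, xs),
            )
        )
        next_id += 1
    return colonies


def compute_phenotype(cells: list[CellRecord], colonies: list[ColonyRecord]) -> WellPhenotype:
    """Reduce per-well detections to the six phenotypic parameters.

    Total CSCs count Nanog+ cells *within colonies* only; with no colonies
    the density is reported as 0 together with the explicit ``no_colonies``
    flag so screen matrices stay rectangular.
    """
    total_cells = len(cells)
    total_cafs = sum(1 for c in cells if c.cd90_pos)
    total_cscs = sum(c.nanog_pos_count for c in colonies)
    colony_count = len(colonies)
    total_colony_cells = sum(c.member_count for c in colonies)
    total_area = sum(c.area_um2 for c in colonies)
    if colony_count == 0 or total_area == 0:
        return WellPhenotype(total_cells, total_cafs, 0, 0, 0, 0.0, no_colonies=True)
    return WellPhenotype(
        total_cells,
        total_cafs,
        total_cscs,
        colony_count,
        total_colony_cells,
        total_colony_cells / total_area,
    )


def score_well(
    montage: WellMontage, params: ScoringParams | None = None
) -> tuple[WellPhenotype, list[CellRecord], list[ColonyRecord]]:
    """Full per-well pipeline: filter, detect, build colonies, summarise."""
    params = params or ScoringParams()
    stem = preprocess_stemness(montage, params)
    cells = detect_cells(montage, params, stemness_filtered=stem)
    colonies = identify_colonies(cells, montage, params, stemness_filtered=stem)
    return compute_phenotype(cells, colonies), cells, colonies
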