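"""Synapse and perisomatic-terminal quantification from binary masks.

Putative synapses are defined geometrically: connected components of the
pre- and postsynaptic marker masks ("puncta") are reduced to centroids,
tiny components (<= 2 px) are discarded, and a presynaptic punctum counts
as a synapse if some postsynaptic centroid lies within 1 µm.  Perisomatic
inhibitory (e.g. parvalbumin-positive) innervation is quantified as marker
area inside an annulus around a traced soma outline, normalized to the
soma perimeter; interneuron density is a count per area (or volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon
from shapely import contains_xy
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "PunctaMask",
    "Punctum",
    "SomaOutline",
    "extract_puncta",
    "count_synapses",
    "perisomatic_area",
    "cell_density",
]

MIN_PUNCTUM_AREA_PX = 3  # components of 2 px or less are excluded
SYNAPSE_MAX_DIST_UM = 1.0
DEFAULT_DILATION_UM = 1.5


@dataclass
class PunctaMask:
    """Binary marker image with physical calibration."""

    image: np.ndarray
    pixel_size: float  # um / px
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("image must be a nonempty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        vals = np.unique(self.image)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary (0/1)")
        self.image = self.image.astype(bool)


@dataclass
class Punctum:
    """One connected marker blob: centroid in µm, pixel area."""

    id: int
    centroid: tuple  # (x_um, y_um)
    area_px: int


@dataclass
class SomaOutline:
    """Manually traced cell-body outline with an annulus width for the
    perisomatic region."""

    cell_id: str
    polygon: np.ndarray  # (n, 2) vertices in um, closed implicitly
    dilation: float = DEFAULT_DILATION_UM  # um

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[0] < 3 or self.polygon.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        poly = Polygon(self.polygon)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("polygon must be simple and enclose a positive area")

    @property
    def shape(self) -> Polygon:
        return Polygon(self.polygon)

    @property
    def perimeter(self) -> float:
        return float(self.shape.length)


def extract_puncta(mask: PunctaMask,
                   min_area_px: int = MIN_PUNCTUM_AREA_PX) -> list[Punctum]:
    """Connected components (8-connectivity) of at least ``min_area_px``.

    Centroids are converted to µm with the mask's pixel size; components of
    2 px or less are excluded by default, matching the particle-analysis
    convention for puncta counting.
    """
    labels = cc_label(mask.image, connectivity=2)
    out: list[Punctum] = []
    for props in regionprops(labels):
        if props.area < min_area_px:
            continue
        cy, cx = props.centroid
        out.append(Punctum(id=int(props.label),
                           centroid=(float(cx * mask.pixel_size),
                                     float(cy * mask.pixel_size)),
                           area_px=int(props.area)))
    return out


def count_synapses(pre: list[Punctum], post: list[Punctum],
                   max_dist: float = SYNAPSE_MAX_DIST_UM,
                   mode: str = "pre") -> tuple[int, list[int]]:
    """Count putative synapses by centroid distance.

    Every pre/post centroid distance is computed (Euclidean); a distance of
    ``max_dist`` µm or less counts.  With ``mode="pre"`` (default) a synapse
    is a presynaptic punctum with at least one post partner, each counted
    once; ``mode="pairs"`` counts every qualifying pre/post pair instead.
    Returns the count and the matched pre punctum ids.
    """
    if not pre or not post:
        return 0, []
    d = cdist(np.array([p.centroid for p in pre]),
              np.array([p.centroid for p in post]))
    hits = d <= max_dist
    matched = [p.id for p, h in zip(pre, hits.any(axis=1)) if h]
    if mode == "pre":
        return len(matched), matched
    if mode == "pairs":
        return int(hits.sum()), matched
    raise ValueError(f"unknown counting mode {mode!r}")


def perisomatic_area(soma: SomaOutline, pv: PunctaMask) -> float:
    """Marker area per unit soma perimeter (µm²/µm) in the perisomatic annulus.

    The annulus is the region between the soma polygon and its outward
    dilation by ``soma.dilation`` µm.  Marker-positive pixels whose centers
    fall inside the annulus contribute their pixel area.
    """
    if soma.perimeter <= 0:
        raise ValueError("soma outline has zero perimeter")
    poly = soma.shape
    annulus = poly.buffer(soma.dilation).difference(poly)
    rows, cols = np.nonzero(pv.image)
    if rows.size == 0:
        return 0.0
    # pixel-center convention: pixel (r, c) covers [c, c+1) x [r, r+1) px
    xs = (cols + 0.5) * pv.pixel_size
    ys = (rows + 0.5) * pv.pixel_size
    inside = contains_xy(annulus, xs, ys)
    area_um2 = float(inside.sum()) * pv.pixel_size ** 2
    return area_um2 / soma.perimeter


def cell_density(n_cells: int, region_area_um2: float,
                 section_thickness_um: float | None = None) -> float:
    """Cells per mm² (or per mm³ if a section thickness in µm is given)."""
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    if region_area_um2 <= 0:
        raise ValueError("region_area must be positive")
    per_mm2 = n_cells / (region_area_um2 / 1e6)
    if section_thickness_um is None:
        return per_mm2
    if section_thickness_um <= 0:
        raise ValueError("section_thickness must be positive")
    return per_mm2 / (section_thickness_um / 1e3)
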