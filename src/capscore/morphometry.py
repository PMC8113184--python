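"""Geometric feature measurement on annotated capillary cross-sections.

Annotations (e.g. drawn in QuPath on large-scale EM sections digitised at
7.3 nm pixel size) describe one capillary as a set of closed polygons in
section-plane nm coordinates: the lumen, the outer endothelial contour,
one or more nested basement-membrane (BM) layer rings, pericyte/endothelial
process profiles, and point-plus-diameter marks for tubuloreticular
inclusions.  This module turns those polygons into the raw quantities the
ordinal rubric needs:

* BM thickness — radial rays are cast from the lumen centroid (with a
  pole-of-inaccessibility fallback for non-star-shaped lumina) and the
  length of each ray inside the union of BM polygons is measured; the
  per-capillary thickness is a configurable summary (median by default)
  over the rays that hit the BM.
* BM layer count — the number of nested layer rings.
* process count and prominence — processes intersecting a peri-capillary
  annulus outside the outermost BM are counted, and their angular coverage
  of the perimeter is banded into focal_small / prominent / very_prominent.
* endothelial area — outer endothelial area minus lumen area, in µm².

All measurements operate on continuous nm coordinates and are invariant
under rigid motions of the annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import polylabel, unary_union

from .config import MorphometryConfig, RubricConfig, TriSizeClasses
from .errors import AnnotationError, InvalidInputError, MeasurementError
from .rubric import CapillaryFeatures, ProcessProminence, SizeClass, TriObservation

__all__ = [
    "ProcessAnnotation",
    "TriMark",
    "CapillaryGeometry",
    "measure_bm_thickness",
    "count_bm_layers",
    "count_processes",
    "measure_endothelial_area",
    "extract_features",
]

logger = logging.getLogger(__name__)

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class ProcessAnnotation:
    """One pericyte/endothelial process profile, with an optional manual
    size tag ('small' or 'large')."""

    polygon: Polygon
    size_tag: str | None = None


@dataclass(frozen=True)
class TriMark:
    """A tubuloreticular inclusion marked as centre point + max diameter."""

    x_nm: float
    y_nm: float
    diameter_nm: float


@dataclass
class CapillaryGeometry:
    """Polygonal annotation of one capillary cross-section (coordinates nm).

    ``bm_layers`` are ordered innermost first; each layer is a ring-shaped
    polygon (exterior with an interior hole) or a simple polygon for a
    filled lamina.  ``endothelium_outer`` may be ``None`` for degraded
    capillaries where only the BM "sack" remains.
    """

    lumen: Polygon
    endothelium_outer: Polygon | None = None
    bm_layers: Sequence[Polygon] = ()
    processes: Sequence[ProcessAnnotation] = ()
    tri_marks: Sequence[TriMark] = ()
    pixel_size_nm: float = 7.3
    capillary_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise InvalidInputError("pixel_size_nm must be positive")
        if self.lumen is None or self.lumen.is_empty:
            raise AnnotationError(f"capillary {self.capillary_id!r}: lumen polygon required")
        if not self.lumen.is_valid:
            raise AnnotationError(f"capillary {self.capillary_id!r}: invalid lumen polygon")
        self.bm_layers = list(self.bm_layers)
        self.processes = list(self.processes)
        self.tri_marks = list(self.tri_marks)


def _ray_origin(geom: CapillaryGeometry) -> Point:
    """Lumen centroid, falling back to the pole of inaccessibility when the
    centroid falls outside a non-star-shaped lumen."""
    centroid = geom.lumen.centroid
    if geom.lumen.contains(centroid):
        return centroid
    logger.warning(
        "capillary %r: lumen centroid outside lumen; using pole of inaccessibility",
        geom.capillary_id,
    )
    return polylabel(geom.lumen, tolerance=max(geom.lumen.bounds[2] - geom.lumen.bounds[0], 1.0) / 100)


def _bm_union(geom: CapillaryGeometry):
    if not geom.bm_layers:
        raise InvalidInputError(
            f"capillary {geom.capillary_id!r}: at least one BM layer polygon required"
        )
    union = unary_union(list(geom.bm_layers))
    return union


def _anchor_angle(geom: CapillaryGeometry, origin: Point) -> float:
    """Ray-fan reference direction: from the origin toward the lumen's first
    exterior vertex.  Anchoring the fan to the annotation itself (rather than
    to the world x-axis) makes the sampled directions co-rotate with the
    contour, so measurements are invariant under rigid motions."""
    x0, y0 = geom.lumen.exterior.coords[0]
    return math.atan2(y0 - origin.y, x0 - origin.x)


def _max_reach(geom: CapillaryGeometry, origin: Point) -> float:
    xs, ys = [], []
    shapes = [geom.lumen, *geom.bm_layers]
    if geom.endothelium_outer is not None:
        shapes.append(geom.endothelium_outer)
    for p in shapes:
        minx, miny, maxx, maxy = p.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    dx = max(abs(v - origin.x) for v in xs)
    dy = max(abs(v - origin.y) for v in ys)
    return 2.0 * math.hypot(dx, dy) + 1.0


def measure_bm_thickness(
    geom: CapillaryGeometry,
    n_rays: int = 36,
    summary: str = "median",
) -> float:
    """Radial-ray BM thickness in nm.

    Casts ``n_rays`` equally spaced rays from the lumen centroid and sums,
    per ray, the length of the ray inside the union of the BM layer
    polygons; returns the ``summary`` statistic (median/mean/max) over rays
    that intersect the BM.  Raises :class:`MeasurementError` if no ray hits.
    """
    if n_rays < 8:
        raise InvalidInputError("n_rays must be >= 8")
    if summary not in ("median", "mean", "max"):
        raise InvalidInputError("summary must be 'median', 'mean' or 'max'")
    union = _bm_union(geom)
    origin = _ray_origin(geom)
    reach = _max_reach(geom, origin)
    angles = _anchor_angle(geom, origin) + np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    lengths = []
    for theta in angles:
        ray = LineString(
            [
                (origin.x, origin.y),
                (origin.x + reach * math.cos(theta), origin.y + reach * math.sin(theta)),
            ]
        )
        seg = ray.intersection(union)
        if not seg.is_empty and seg.length > 0:
            lengths.append(seg.length)
    if not lengths:
        raise MeasurementError(
            f"capillary {geom.capillary_id!r}: no ray intersects the basement membrane"
        )
    arr = np.asarray(lengths)
    if summary == "median":
        return float(np.median(arr))
    if summary == "mean":
        return float(np.mean(arr))
    return float(np.max(arr))


def _filled(polygon: Polygon) -> Polygon:
    """Polygon with interior holes removed (the region enclosed by its
    exterior ring)."""
    return Polygon(polygon.exterior)


def count_bm_layers(geom: CapillaryGeometry) -> int:
    """Number of distinct nested BM layer rings.

    Layers must be nested outward (each layer's exterior encloses the
    previous layer's exterior); overlapping non-nested layers raise
    :class:`AnnotationError`.
    """
    layers = list(geom.bm_layers)
    if not layers:
        raise InvalidInputError(
            f"capillary {geom.capillary_id!r}: at least one BM layer polygon required"
        )
    filled = [_filled(p) for p in layers]
    # sort innermost first by enclosed area, then verify strict nesting
    order = np.argsort([f.area for f in filled])
    for a, b in zip(order[:-1], order[1:]):
        inner, outer = filled[a], filled[b]
        if not outer.buffer(1e-6 * math.sqrt(outer.area)).contains(inner):
            raise AnnotationError(
                f"capillary {geom.capillary_id!r}: BM layer polygons are not nested"
            )
    return len(layers)


def _outer_boundary(geom: CapillaryGeometry) -> Polygon:
    """Filled region out to the outermost BM layer (or the endothelium when
    no BM layer is annotated)."""
    if geom.bm_layers:
        filled = [_filled(p) for p in geom.bm_layers]
        return max(filled, key=lambda f: f.area)
    if geom.endothelium_outer is not None:
        return _filled(geom.endothelium_outer)
    raise InvalidInputError(
        f"capillary {geom.capillary_id!r}: no BM layer or endothelium to bound the annulus"
    )


def count_processes(
    geom: CapillaryGeometry,
    annulus_width_nm: float = 1000.0,
    coverage_cuts: tuple[float, float] = (0.25, 0.75),
    n_probe_angles: int = 720,
) -> tuple[int, ProcessProminence]:
    """Count ensheathing processes and grade their prominence.

    A process counts if its polygon intersects the peri-capillary annulus of
    width ``annulus_width_nm`` immediately outside the outermost BM layer.
    Prominence is the fraction of equally spaced probe directions (from the
    lumen centroid) whose ray meets a counted process: below
    ``coverage_cuts[0]`` → focal_small, between the cuts → prominent, above
    ``coverage_cuts[1]`` → very_prominent.
    """
    if annulus_width_nm <= 0:
        raise InvalidInputError("annulus_width_nm must be positive")
    core = _outer_boundary(geom)
    annulus = core.buffer(annulus_width_nm).difference(core)
    counted = [
        p for p in geom.processes if not p.polygon.is_empty and p.polygon.intersects(annulus)
    ]
    if not counted:
        return 0, ProcessProminence.FOCAL_SMALL
    origin = _ray_origin(geom)
    reach = _max_reach(geom, origin) + annulus_width_nm
    union = unary_union([p.polygon for p in counted])
    angles = _anchor_angle(geom, origin) + np.linspace(
        0.0, 2.0 * np.pi, n_probe_angles, endpoint=False
    )
    starts = np.full((n_probe_angles, 2), (origin.x, origin.y))
    ends = starts + reach * np.c_[np.cos(angles), np.sin(angles)]
    rays = shapely.linestrings(np.stack([starts, ends], axis=1))
    coverage = float(np.mean(shapely.intersects(rays, union)))
    if coverage < coverage_cuts[0]:
        prominence = ProcessProminence.FOCAL_SMALL
    elif coverage <= coverage_cuts[1]:
        prominence = ProcessProminence.PROMINENT
    else:
        prominence = ProcessProminence.VERY_PROMINENT
    return len(counted), prominence


def measure_endothelial_area(geom: CapillaryGeometry) -> float:
    """Endothelial cross-sectional area in µm²: area enclosed by the outer
    endothelial contour minus the lumen area."""
    if geom.endothelium_outer is None:
        raise MeasurementError(
            f"capillary {geom.capillary_id!r}: no endothelial contour annotated"
        )
    area_nm2 = _filled(geom.endothelium_outer).area - _filled(geom.lumen).area
    if area_nm2 < -1e-6 * _filled(geom.lumen).area:
        raise AnnotationError(
            f"capillary {geom.capillary_id!r}: endothelial contour smaller than lumen "
            "(contours swapped?)"
        )
    return max(area_nm2, 0.0) / NM2_PER_UM2


def extract_features(
    geom: CapillaryGeometry,
    config: RubricConfig | MorphometryConfig | None = None,
    tri_sizes: TriSizeClasses | None = None,
) -> CapillaryFeatures:
    """Compose the geometric measurements into a raw feature record.

    Measurements that fail (e.g. the endothelium of a degraded capillary)
    are recorded as missing rather than aborting the capillary; TRI marks
    are classified into small/medium/large by diameter.
    """
    if isinstance(config, RubricConfig):
        morpho = config.morphometry
        tri_sizes = tri_sizes or config.tri_sizes
    else:
        morpho = config or MorphometryConfig()
        tri_sizes = tri_sizes or TriSizeClasses()

    thickness: float | None
    layers: int | None
    try:
        thickness = measure_bm_thickness(geom, morpho.n_rays, morpho.thickness_summary)
    except (MeasurementError, InvalidInputError) as exc:
        logger.warning("capillary %r: BM thickness missing (%s)", geom.capillary_id, exc)
        thickness = None
    try:
        layers = count_bm_layers(geom)
    except (InvalidInputError,) as exc:
        logger.warning("capillary %r: BM layer count missing (%s)", geom.capillary_id, exc)
        layers = None

    try:
        area = measure_endothelial_area(geom)
    except MeasurementError as exc:
        logger.warning("capillary %r: endothelial area missing (%s)", geom.capillary_id, exc)
        area = None

    count: int | None
    try:
        count, prominence = count_processes(
            geom,
            annulus_width_nm=morpho.annulus_width_nm,
            coverage_cuts=(morpho.coverage_focal_max, morpho.coverage_prominent_max),
        )
    except InvalidInputError as exc:
        logger.warning("capillary %r: process count missing (%s)", geom.capillary_id, exc)
        count, prominence = None, ProcessProminence.PROMINENT

    tri_obs: list[TriObservation] = []
    counts = {SizeClass.SMALL: 0, SizeClass.MEDIUM: 0, SizeClass.LARGE: 0}
    for mark in geom.tri_marks:
        counts[SizeClass(tri_sizes.classify(mark.diameter_nm))] += 1
    for size, c in counts.items():
        if c:
            tri_obs.append(TriObservation(size_class=size, count=c))

    return CapillaryFeatures(
        bm_thickness_nm=thickness,
        bm_layer_count=layers,
        endothelial_area_um2=area,
        process_count=count,
        process_prominence=prominence,
        tri=tuple(tri_obs),
        degraded=geom.endothelium_outer is None,
    )
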