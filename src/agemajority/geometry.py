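"""Planar geometry for hand/wrist skeletal-maturity measurement.

Skeletal maturity of the hand/wrist is summarised by the dimensionless
ratio Bo/Ca: Bo is the area jointly covered by the eight carpal bones
plus the ulnar and radial epiphyses, with any overlap between bones
counted only once (i.e. the area of the set union), and Ca is the area
of the delineated carpal region.  All coordinates are millimetres and
areas mm²; full fusion corresponds to Bo/Ca approaching 1.

Polygons are simple (non-self-intersecting) closed vertex chains; the
vertex orientation does not matter.  Exact polygon union is delegated to
:mod:`shapely`'s clipping engine.
"""

from __future__ import annotations

from collections.abc import Sequence

import shapely
from pydantic import BaseModel, model_validator

from .errors import InvalidGeometryError, MissingMeasurementError

__all__ = [
    "Polygon2D",
    "CarpalRadiograph",
    "polygon_area",
    "union_area",
    "compute_bo_ca",
    "hand_complete_from_ratio",
]


class Polygon2D(BaseModel, frozen=True):
    """A simple polygon given as an ordered vertex list in mm, implicitly closed.

    Invariants (validated on construction): at least three vertices,
    no self-intersection, strictly positive area.
    """

    vertices: tuple[tuple[float, float], ...]

    @model_validator(mode="after")
    def _check_geometry(self) -> "Polygon2D":
        if len(self.vertices) < 3:
            raise InvalidGeometryError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid:
            raise InvalidGeometryError(
                f"invalid polygon ({shapely.is_valid_reason(poly)})"
            )
        if poly.area <= 0.0:
            raise InvalidGeometryError("polygon encloses no area")
        return self

    def as_shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


class CarpalRadiograph(BaseModel, frozen=True):
    """Digitised regions of a left hand/wrist radiograph.

    ``bone_regions`` holds the outlines of the eight carpal bones plus
    the ulnar and radial epiphyses as delineated; ``carpal_region`` is
    the outline whose area is Ca.
    """

    bone_regions: tuple[Polygon2D, ...]
    carpal_region: Polygon2D

    @model_validator(mode="after")
    def _check_bone_sizes(self) -> "CarpalRadiograph":
        ca = polygon_area(self.carpal_region)
        for i, bone in enumerate(self.bone_regions):
            if polygon_area(bone) > ca:
                raise InvalidGeometryError(
                    f"bone region {i} is larger than the carpal region"
                )
        return self


def polygon_area(p: Polygon2D) -> float:
    """Absolute enclosed area of ``p`` in mm², independent of orientation."""
    return float(p.as_shapely().area)


def union_area(ps: Sequence[Polygon2D]) -> float:
    """Area of the set union of ``ps`` in mm²; overlap is counted once.

    An empty sequence has union area 0 by convention.  The result never
    exceeds the sum of the individual areas, with equality exactly when
    the polygons are pairwise disjoint.
    """
    if len(ps) == 0:
        return 0.0
    return float(shapely.unary_union([p.as_shapely() for p in ps]).area)


def compute_bo_ca(r: CarpalRadiograph) -> float:
    """Bo/Ca ratio: union area of the bone regions over the carpal area.

    Raises
    ------
    MissingMeasurementError
        If no bone regions were delineated (unmeasurable radiograph).
    """
    if len(r.bone_regions) == 0:
        raise MissingMeasurementError("no bone regions delineated")
    return union_area(r.bone_regions) / polygon_area(r.carpal_region)


def hand_complete_from_ratio(bo_ca: float, cutoff: float = 1.0) -> bool:
    """Derive hand/wrist completeness from a Bo/Ca ratio.

    The decision flow uses the hand only as a complete/incomplete gate.
    When completeness is not supplied directly as a flag it is derived
    as ``bo_ca >= cutoff``; the default cutoff 1.0 demands full fusion.
    """
    return bo_ca >= cutoff
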