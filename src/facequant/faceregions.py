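"""Partition a 68-point landmark set into six facial areas.

The six areas — left eye, right eye, nose, mouth, left cheek, right
cheek — follow the anatomical (subject-side) naming convention of the
landmark scheme: "right" regions are built from the subject's right-side
landmarks (image-left for an upright, front-facing annotation).

Construction convention
-----------------------
* Eyes: convex hull of the eye landmarks united with the brow landmarks
  on the same side, dilated outward by 5% of the inter-ocular distance.
* Nose: convex hull of landmarks 27-35, dilated likewise.
* Mouth: convex hull of landmarks 48-67, dilated likewise.
* Cheeks: convex hull of the jawline on that side together with the
  cheek-facing halves of the eye, nose and mouth polygons, then clipped
  against the eye/nose/mouth polygons (which take precedence).

All constructions use only convex hulls, similarity-covariant dilation
and boolean clipping, so the partition is equivariant under similarity
transforms of the landmarks and mirror-symmetric under a canonical
horizontal flip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

from .landmarks import (
    JAW,
    LEFT_BROW,
    LEFT_EYE,
    LandmarkSet,
    MOUTH,
    NOSE,
    RIGHT_BROW,
    RIGHT_EYE,
)

REGION_NAMES = ("left-eye", "right-eye", "nose", "mouth", "left-cheek", "right-cheek")

#: Boundary-pixel precedence when regions touch: eyes > nose > mouth > cheeks.
REGION_PRECEDENCE = ("left-eye", "right-eye", "nose", "mouth", "left-cheek", "right-cheek")


class DegenerateLandmarksError(ValueError):
    """Raised when a region cannot be built from the given landmarks."""

    def __init__(self, region: str, reason: str):
        self.region = region
        super().__init__(f"cannot construct region '{region}': {reason}")


@dataclass(frozen=True)
class RegionPartition:
    """Six named simple polygons partitioning the face."""

    regions: dict  # name -> (n, 2) float vertex array
    source_image_size: int

    def polygon(self, name: str) -> Polygon:
        if name not in self.regions:
            raise KeyError(f"unknown region name: {name!r}")
        return Polygon(self.regions[name])

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_image_size": self.source_image_size,
                "regions": {k: np.asarray(v).tolist() for k, v in self.regions.items()},
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "RegionPartition":
        d = json.loads(s)
        return cls(
            regions={k: np.asarray(v, dtype=float) for k, v in d["regions"].items()},
            source_image_size=int(d["source_image_size"]),
        )


@dataclass(frozen=True)
class RegionMask:
    name: str
    mask: np.ndarray  # (H, W) bool


def _hull(points: np.ndarray, region: str) -> Polygon:
    hull = MultiPoint([tuple(p) for p in points]).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise DegenerateLandmarksError(region, "landmark hull has zero area (collinear points)")
    return hull


def _largest(geom) -> Polygon:
    if isinstance(geom, Polygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon) and g.area > 0]
    if not polys:
        raise DegenerateLandmarksError("cheek", "clipping left no positive-area polygon")
    return max(polys, key=lambda g: g.area)


def _vertices(poly: Polygon) -> np.ndarray:
    ring = np.asarray(orient(poly, sign=1.0).exterior.coords)[:-1]
    return ring


def partition_face(landmarks: LandmarkSet) -> RegionPartition:
    """Build the six facial areas from one landmark set.

    Raises
    ------
    DegenerateLandmarksError
        If any region's defining landmarks are collinear or the
        resulting polygon is empty.
    """
    pts = landmarks.points

    eye_r_c = pts[RIGHT_EYE].mean(axis=0)
    eye_l_c = pts[LEFT_EYE].mean(axis=0)
    interocular = float(np.linalg.norm(eye_l_c - eye_r_c))
    if interocular <= 0:
        raise DegenerateLandmarksError("eyes", "coincident eye centroids")
    dilate = 0.05 * interocular

    # Face-intrinsic axes: u points from the right eye toward the left eye
    # (the face's lateral axis), v is perpendicular, oriented toward the chin.
    u = (eye_l_c - eye_r_c) / interocular
    v = np.array([-u[1], u[0]])
    chin_dir = pts[8] - (eye_r_c + eye_l_c) / 2
    if np.dot(v, chin_dir) < 0:
        v = -v

    def dilated_hull(idx, region):
        return _hull(pts[idx], region).buffer(dilate, quad_segs=4)

    # the eye landmarks themselves must span an area (collinear or
    # coincident eye points are a degenerate annotation even when the
    # brow points would still give the united hull positive area)
    _hull(pts[RIGHT_EYE], "right-eye")
    _hull(pts[LEFT_EYE], "left-eye")
    eye_right = dilated_hull(RIGHT_EYE + RIGHT_BROW, "right-eye")
    eye_left = dilated_hull(LEFT_EYE + LEFT_BROW, "left-eye")
    nose = dilated_hull(NOSE, "nose")
    mouth = dilated_hull(MOUTH, "mouth")

    eyes = eye_right.union(eye_left)
    nose_c = _largest(nose.difference(eyes))
    mouth_c = _largest(mouth.difference(eyes.union(nose_c)))

    def half(poly: Polygon, axis: np.ndarray, sign: float) -> np.ndarray:
        verts = _vertices(poly)
        rel = (verts - verts.mean(axis=0)) @ axis
        sel = verts[sign * rel >= 0]
        return sel

    def cheek(jaw_idx, eye_poly, lateral_sign, region):
        support = np.vstack(
            [
                pts[jaw_idx],
                half(eye_poly, v, +1.0),  # lower edge of the eye area
                half(nose, u, lateral_sign),  # lateral edge of the nose
                half(mouth, u, lateral_sign),  # lateral edge of the mouth
            ]
        )
        raw = _hull(support, region)
        clipped = raw.difference(shapely.union_all([eyes, nose, mouth]))
        poly = _largest(clipped)
        if poly.area <= 0:
            raise DegenerateLandmarksError(region, "empty after clipping")
        return poly

    # subject's right = smaller u-coordinate side = jaw points 1-7
    cheek_right = cheek(JAW[1:8], eye_right, -1.0, "right-cheek")
    cheek_left = cheek(JAW[9:16], eye_left, +1.0, "left-cheek")

    regions = {
        "left-eye": _vertices(eye_left),
        "right-eye": _vertices(eye_right),
        "nose": _vertices(nose_c),
        "mouth": _vertices(mouth_c),
        "left-cheek": _vertices(cheek_left),
        "right-cheek": _vertices(cheek_right),
    }
    return RegionPartition(regions=regions, source_image_size=landmarks.image_size)


def region_mask(partition: RegionPartition, name: str, image_size: int | None = None) -> RegionMask:
    """Rasterize one region: a pixel is inside iff its (integer) center
    is covered by the polygon, boundary included."""
    if name not in REGION_NAMES:
        raise KeyError(f"unknown region name: {name!r}")
    size = image_size if image_size is not None else partition.source_image_size
    poly = partition.polygon(name)
    mask = np.zeros((size, size), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = max(0, int(np.floor(minx))), min(size - 1, int(np.ceil(maxx)))
    y0, y1 = max(0, int(np.floor(miny))), min(size - 1, int(np.ceil(maxy)))
    if x1 >= x0 and y1 >= y0:
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        pts = shapely.points(xs.ravel(), ys.ravel())
        inside = shapely.covers(poly, pts).reshape(xs.shape)
        mask[y0:y1 + 1, x0:x1 + 1] = inside
    return RegionMask(name=name, mask=mask)


def region_masks(partition: RegionPartition, image_size: int | None = None) -> dict:
    return {n: region_mask(partition, n, image_size).mask for n in REGION_NAMES}


def assign_contour(partition: RegionPartition, contour, image_size: int | None = None,
                   masks: dict | None = None) -> set:
    """Region names whose rasterized area overlaps the contour's filled
    pixels by at least one pixel.  A feature straddling a boundary is
    counted in every region it touches; a feature outside all six areas
    yields the empty set.

    ``masks`` may carry precomputed region masks to amortize
    rasterization over many contours on the same face.
    """
    if masks is None:
        masks = region_masks(partition, image_size)
    ys, xs = contour.pixels[:, 0], contour.pixels[:, 1]
    hit = set()
    for name, m in masks.items():
        if m[ys, xs].any():
            hit.add(name)
    return hit
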