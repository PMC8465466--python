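"""68-point facial landmark sets and the canonical template face.

The 68-point annotation scheme is the de-facto standard for 2-D face
alignment: jaw 0-16 (image-left temple, around the chin, to image-right
temple), brows 17-26, nose 27-35 (bridge 27-30, base 31-35), eyes 36-47
(36-41 the subject's right eye, i.e. image-left; 42-47 the left eye),
mouth 48-67 (outer lip 48-59, inner lip 60-67).

Coordinates are pixel coordinates: x grows rightward, y downward, and
pixel centers sit at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_LANDMARKS = 68

JAW = list(range(0, 17))
RIGHT_BROW = list(range(17, 22))
LEFT_BROW = list(range(22, 27))
NOSE = list(range(27, 36))
RIGHT_EYE = list(range(36, 42))
LEFT_EYE = list(range(42, 48))
MOUTH = list(range(48, 68))

#: Index permutation realized by a horizontal flip of the annotated face:
#: jaw and brows reverse, nose base reverses, eyes and lips swap sides.
FLIP_PERMUTATION = (
    list(range(16, -1, -1))
    + list(range(26, 16, -1))
    + [27, 28, 29, 30]
    + [35, 34, 33, 32, 31]
    + [45, 44, 43, 42, 47, 46]
    + [39, 38, 37, 36, 41, 40]
    + [54, 53, 52, 51, 50, 49, 48, 59, 58, 57, 56, 55]
    + [64, 63, 62, 61, 60, 67, 66, 65]
)


@dataclass(frozen=True)
class LandmarkSet:
    """An ordered set of 68 facial landmark points for one image."""

    points: np.ndarray  # (68, 2) float array of (x, y)
    image_size: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected {N_LANDMARKS} (x, y) points, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        if pts.min() < 0 or pts.max() > self.image_size - 1:
            raise ValueError("landmark points must lie within image bounds")
        object.__setattr__(self, "points", pts)

    def __getitem__(self, idx):
        return self.points[idx]

    def mirror(self) -> "LandmarkSet":
        """Reflect about the vertical image midline, re-indexing canonically."""
        pts = self.points.copy()
        pts[:, 0] = (self.image_size - 1) - pts[:, 0]
        return LandmarkSet(points=pts[FLIP_PERMUTATION], image_size=self.image_size)

    def transformed(self, scale: float, image_size: int) -> "LandmarkSet":
        return LandmarkSet(points=self.points * scale, image_size=image_size)

    def to_dict(self) -> dict:
        return {"points": self.points.tolist(), "image_size": self.image_size}

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(points=np.asarray(d["points"], dtype=float), image_size=int(d["image_size"]))


# Template landmark geometry in unit face coordinates ([0, 1] x [0, 1]).
def _template_unit_points() -> np.ndarray:
    pts = np.zeros((N_LANDMARKS, 2))
    # jaw: lower half-ellipse from image-left temple to image-right temple
    phi = np.linspace(0.0, np.pi, 17)
    pts[JAW, 0] = 0.5 - 0.37 * np.cos(phi)
    pts[JAW, 1] = 0.45 + 0.48 * np.sin(phi)
    # brows: gentle arcs above each eye
    bx = np.linspace(0.20, 0.42, 5)
    pts[RIGHT_BROW, 0] = bx
    pts[RIGHT_BROW, 1] = 0.30 - 0.02 * np.sin(np.linspace(0, np.pi, 5))
    pts[LEFT_BROW, 0] = 1.0 - bx[::-1]
    pts[LEFT_BROW, 1] = pts[RIGHT_BROW, 1][::-1]
    # nose bridge and base
    pts[27:31] = [(0.5, 0.38), (0.5, 0.46), (0.5, 0.54), (0.5, 0.60)]
    pts[31:36] = [(0.42, 0.645), (0.46, 0.66), (0.5, 0.665), (0.54, 0.66), (0.58, 0.645)]
    # eyes: almond hexagons
    pts[RIGHT_EYE] = [
        (0.24, 0.400), (0.28, 0.385), (0.33, 0.385),
        (0.37, 0.400), (0.33, 0.415), (0.28, 0.415),
    ]
    pts[LEFT_EYE] = [
        (0.63, 0.400), (0.67, 0.385), (0.72, 0.385),
        (0.76, 0.400), (0.72, 0.415), (0.67, 0.415),
    ]
    # outer lip
    pts[48:60] = [
        (0.36, 0.780), (0.41, 0.755), (0.46, 0.745), (0.50, 0.750),
        (0.54, 0.745), (0.59, 0.755), (0.64, 0.780), (0.59, 0.810),
        (0.54, 0.825), (0.50, 0.830), (0.46, 0.825), (0.41, 0.810),
    ]
    # inner lip
    pts[60:68] = [
        (0.40, 0.780), (0.46, 0.770), (0.50, 0.772), (0.54, 0.770),
        (0.60, 0.780), (0.54, 0.790), (0.50, 0.793), (0.46, 0.790),
    ]
    return pts


_TEMPLATE_UNIT = _template_unit_points()


def template_landmarks(image_size: int = 224) -> LandmarkSet:
    """Canonical upright template face scaled to an ``image_size`` square.

    The face occupies the central ~86% of the frame so that landmark
    jitter cannot push points out of bounds for reasonable jitter levels.
    """
    margin = 0.07
    pts = (_TEMPLATE_UNIT * (1 - 2 * margin) + margin) * (image_size - 1)
    return LandmarkSet(points=pts, image_size=image_size)
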