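"""Quantify where saliency concentrates on the face.

The six-step procedure turns a normalized saliency heatmap into
per-region feature presence:

1. partition the face into six areas from its 68 landmarks,
2. binarize the heatmap at a threshold (default 0.5 of the normalized
   range; Otsu available),
3. smooth with a 3x3 Gaussian kernel and re-threshold, removing
   single-pixel speckle,
4. mark the contours (8-connected components) of the cleaned mask,
5. discard contours whose bounding box is narrower or shorter than a
   minimum size (10 px in the reference 224 px frame) — too small to be
   a valid facial feature,
6. flag, per image and per region, whether any surviving contour
   overlaps that region; aggregate flags into per-group counts and
   proportions and compare the groups region-by-region with a 2x2
   chi-square test.

"Appearance" is per-image presence: a region's count n is the number of
images in the group with at least one feature touching that region, and
its proportion is n/N with N the group size.  A feature straddling a
region boundary is counted in each region it touches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from decimal import Decimal, ROUND_HALF_UP

from . import faceregions, screenstats
from .faceregions import REGION_NAMES

#: 3x3 binomial approximation of a Gaussian kernel (sigma from kernel size).
GAUSS_3X3 = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float) / 16.0

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class Contour:
    """One connected component of the binary saliency mask."""

    pixels: np.ndarray  # (n, 2) int array of (row, col) filled pixels
    boundary: np.ndarray  # (m, 2) ordered closed boundary trace (row, col)
    bbox: tuple  # (x_min, y_min, width, height)
    filled_area: int


@dataclass(frozen=True)
class RegionHits:
    image_id: str
    flags: dict  # region name -> bool

    def __post_init__(self):
        if set(self.flags) != set(REGION_NAMES):
            raise ValueError("RegionHits must carry exactly the six canonical regions")


def binarize_heatmap(heatmap, threshold: float = 0.5) -> np.ndarray:
    """Pixel true iff heatmap value >= threshold.

    ``threshold`` may be the string ``"otsu"`` to derive it from the
    heatmap's histogram instead of the fixed normalized-range fraction.
    """
    values = heatmap.values if hasattr(heatmap, "values") else np.asarray(heatmap)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(values)) if values.max() > values.min() else 0.5
    elif not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    return values >= threshold


def smooth_threshold(binary: np.ndarray) -> np.ndarray:
    """3x3 Gaussian blur of the 0/1 raster followed by re-thresholding at
    0.5.  An isolated true pixel blurs to 0.25 at its own position and is
    removed; solid blobs of 3x3 and larger keep their interiors."""
    blurred = ndimage.convolve(binary.astype(float), GAUSS_3X3, mode="constant", cval=0.0)
    return blurred >= 0.5


def _trace_boundary(mask: np.ndarray, offset=(0, 0)) -> np.ndarray:
    """Moore-neighbor boundary trace of a single connected component,
    returned as an ordered closed loop of (row, col) pixels."""
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # top-most, then left-most
    if len(rows) == 1:
        return np.array([start]) + offset
    # clockwise Moore neighborhood starting from west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]

    def inside(p):
        return 0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1] and mask[p]

    trace = [start]
    prev_dir = 0  # came from the west
    cur = start
    for _ in range(8 * mask.size):
        found = False
        for k in range(8):
            d = (prev_dir + k) % 8
            nxt = (cur[0] + nbrs[d][0], cur[1] + nbrs[d][1])
            if inside(nxt):
                trace.append(nxt)
                # re-enter from the neighbor we backtracked past
                prev_dir = (d + 5) % 8
                cur = nxt
                found = True
                break
        if not found:  # isolated pixel (cannot happen for len > 1)
            break
        if cur == start and len(trace) > 2:
            break
    return np.asarray(trace[:-1] if trace[-1] == start else trace) + offset


def extract_contours(binary: np.ndarray) -> list:
    """One contour per 8-connected component of the binary raster."""
    labeled, n = ndimage.label(binary, structure=EIGHT_CONNECTED)
    contours = []
    for sl, lab in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        local = labeled[sl] == lab
        rows, cols = np.nonzero(local)
        r0, c0 = sl[0].start, sl[1].start
        pixels = np.column_stack([rows + r0, cols + c0])
        bbox = (int(cols.min() + c0), int(rows.min() + r0),
                int(cols.max() - cols.min() + 1), int(rows.max() - rows.min() + 1))
        boundary = _trace_boundary(local, offset=(r0, c0))
        contours.append(Contour(pixels=pixels, boundary=boundary,
                                bbox=bbox, filled_area=int(local.sum())))
    return contours


def filter_contours(contours, min_size: int = 10) -> list:
    """Keep a contour iff its bounding box is at least ``min_size`` pixels
    in BOTH width and height (strictly smaller in either is discarded)."""
    return [c for c in contours if c.bbox[2] >= min_size and c.bbox[3] >= min_size]


def quantify_heatmap(heatmap, partition, threshold=0.5, min_size: int = 10,
                     image_id: str = "", masks: dict | None = None) -> RegionHits:
    """Run steps 2-6 for one image: heatmap -> per-region presence flags."""
    binary = binarize_heatmap(heatmap, threshold)
    cleaned = smooth_threshold(binary)
    contours = filter_contours(extract_contours(cleaned), min_size)
    if masks is None:
        size = cleaned.shape[0]
        masks = faceregions.region_masks(partition, size)
    flags = {name: False for name in REGION_NAMES}
    for c in contours:
        for name in faceregions.assign_contour(partition, c, masks=masks):
            flags[name] = True
    return RegionHits(image_id=image_id, flags=flags)


def count_hits(heatmaps, partitions, image_ids=None, threshold=0.5,
               min_size: int = 10) -> list:
    """Per-region presence flags for a batch of images."""
    if len(heatmaps) != len(partitions):
        raise ValueError("need exactly one partition per heatmap")
    if image_ids is None:
        image_ids = [f"img{i:05d}" for i in range(len(heatmaps))]
    return [
        quantify_heatmap(h, p, threshold=threshold, min_size=min_size, image_id=i)
        for h, p, i in zip(heatmaps, partitions, image_ids)
    ]


def _pct(n: int, N: int) -> float:
    return float((Decimal(100 * n) / Decimal(N)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


def aggregate(case_hits, control_hits, chi_square: bool = True) -> pd.DataFrame:
    """Per-region counts, proportions and (optionally) the case-vs-control
    chi-square comparison, one row per facial area.

    Proportions are percentages of the group size, half-up to 2 decimals.
    """
    if not case_hits or not control_hits:
        raise ValueError("both groups must be non-empty")
    n_case, n_control = len(case_hits), len(control_hits)
    rows = []
    for region in REGION_NAMES:
        a = sum(h.flags[region] for h in case_hits)
        c = sum(h.flags[region] for h in control_hits)
        row = {
            "region": region,
            "n_case": a, "N_case": n_case, "p_case": _pct(a, n_case),
            "n_control": c, "N_control": n_control, "p_control": _pct(c, n_control),
        }
        if chi_square:
            res = screenstats.chi_square_2x2(a, n_case - a, c, n_control - c)
            row.update(chi2=res.statistic, p_value=res.p_value, direction=res.direction)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_from_counts(counts: dict, n_case: int, n_control: int) -> pd.DataFrame:
    """Region table from already-tallied counts
    (``counts[region] = (case_hits, control_hits)``)."""
    rows = []
    for region, (a, c) in counts.items():
        res = screenstats.chi_square_2x2(a, n_case - a, c, n_control - c)
        rows.append({
            "region": region,
            "n_case": a, "N_case": n_case, "p_case": _pct(a, n_case),
            "n_control": c, "N_control": n_control, "p_control": _pct(c, n_control),
            "chi2": res.statistic, "p_value": res.p_value, "direction": res.direction,
        })
    return pd.DataFrame(rows)


def hits_frame(hits) -> pd.DataFrame:
    """Per-image presence flags as a DataFrame (image_id + six columns)."""
    return pd.DataFrame(
        [{"image_id": h.image_id, **{k: bool(v) for k, v in h.flags.items()}} for h in hits]
    )
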