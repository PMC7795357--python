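"""Blood-sampling-point localization on the segmented vein network.

The vein mask is thinned to one-pixel centerlines (removing burrs that
confuse corner detection), Harris corners — points where the gradient
structure tensor has two large eigenvalues, i.e. vein junctions — are
detected inside a fingertip collection box, and the corner nearest the
box center is chosen as the blood-sampling point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import SamplingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CornerSet", "SamplingPoint", "FingerAxis", "thin_mask",
    "harris_response", "detect_corners", "collection_box",
    "locate_sampling_point", "infer_finger_axis",
]


@dataclass(frozen=True)
class FingerAxis:
    """Orientation of the finger in the image frame.

    ``axis`` is 'vertical' (finger runs along rows) or 'horizontal';
    ``distal`` names the fingertip end: 'start' (top/left) or 'end'.
    """

    axis: str = "vertical"
    distal: str = "start"


@dataclass
class CornerSet:
    """Detected corner coordinates with their Harris responses, strongest first."""

    points: np.ndarray      # (n, 2) int (row, col)
    responses: np.ndarray   # (n,) float

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SamplingPoint:
    """Chosen blood-collection coordinate and the geometry that produced it."""

    point: tuple[int, int]               # (row, col), original frame
    box: tuple[int, int, int, int]       # half-open (r0, r1, c0, c1)
    fallback: bool = False               # True when no corner was found
    corners: CornerSet | None = None


def thin_mask(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide skeleton of a binary vein mask (Zhang-Suen-class)."""
    from skimage.morphology import skeletonize

    mask = np.asarray(mask) > 0
    if not mask.any():
        logger.warning("thinning an empty mask; returning empty skeleton")
        return np.zeros_like(mask)
    return skeletonize(mask)


def harris_response(image: np.ndarray, k: float = 0.04,
                    sigma: float = 1.5) -> np.ndarray:
    """Harris corner response R = det(M) - k * trace(M)^2.

    M is the Gaussian-windowed structure tensor of the image gradients;
    two large eigenvalues (a junction) give a large positive R, a single
    large eigenvalue (a straight vein edge) gives R <= 0.  Borders are
    reflected so a constant image has exactly zero response everywhere.
    """
    from skimage.feature import structure_tensor

    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("need a 2-D image of at least 3x3 pixels")
    arr, arc, acc = structure_tensor(image, sigma=sigma, mode="reflect",
                                     order="rc")
    det = arr * acc - arc * arc
    trace = arr + acc
    return det - k * trace * trace


def detect_corners(response: np.ndarray, threshold_frac: float = 0.01,
                   nms_radius: int = 5) -> CornerSet:
    """Thresholded local maxima of a corner response map.

    Keeps pixels whose response exceeds ``threshold_frac`` times the
    global maximum and is the largest within ``nms_radius``; returned
    sorted by response, descending.
    """
    response = np.asarray(response, dtype=float)
    if not np.all(np.isfinite(response)):
        raise ValueError("corner response must be finite")
    peak = response.max()
    if peak <= 0:
        return CornerSet(points=np.empty((0, 2), dtype=int),
                         responses=np.empty(0))
    from skimage.feature import peak_local_max

    pts = peak_local_max(response, min_distance=nms_radius,
                         threshold_abs=threshold_frac * peak)
    resp = response[pts[:, 0], pts[:, 1]]
    order = np.argsort(-resp, kind="stable")
    return CornerSet(points=pts[order], responses=resp[order])


def infer_finger_axis(mask: np.ndarray) -> FingerAxis:
    """Finger orientation from the mask's bounding geometry (elongation)."""
    mask = np.asarray(mask) > 0
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return FingerAxis()
    extent_r = rows.max() - rows.min() + 1
    extent_c = cols.max() - cols.min() + 1
    return FingerAxis(axis="vertical" if extent_r >= extent_c
                      else "horizontal", distal="start")


def collection_box(
    shape: tuple[int, int],
    axis_info: FingerAxis,
    config: SamplingConfig | None = None,
) -> tuple[int, int, int, int]:
    """Half-open (r0, r1, c0, c1) collection box at the distal finger end.

    The box extends ``box_rows`` pixels along the finger axis from the
    fingertip and ``box_cols`` across it (centered), clipped to the
    image.
    """
    cfg = config or SamplingConfig()
    h, w = shape
    along, across = cfg.box_rows, cfg.box_cols
    if axis_info.axis == "vertical":
        r0 = 0 if axis_info.distal == "start" else max(0, h - along)
        r1 = min(h, r0 + along)
        c0 = max(0, (w - across) // 2)
        c1 = min(w, c0 + across)
    else:
        c0 = 0 if axis_info.distal == "start" else max(0, w - along)
        c1 = min(w, c0 + along)
        r0 = max(0, (h - across) // 2)
        r1 = min(h, r0 + across)
    return r0, r1, c0, c1


def locate_sampling_point(
    skeleton: np.ndarray,
    finger_axis_info: FingerAxis | None = None,
    config: SamplingConfig | None = None,
) -> SamplingPoint:
    """Pick the blood-sampling point on the thinned vein network.

    Harris corners are detected on the skeleton restricted to the
    fingertip collection box; the corner closest to the box center wins
    (ties: higher response, then row-major order).  With no corner in
    the box the skeleton pixel nearest the box center is returned,
    flagged as a fallback.
    """
    cfg = config or SamplingConfig()
    skeleton = np.asarray(skeleton) > 0
    if not skeleton.any():
        raise ValueError("no vein network found: the skeleton is empty")
    axis = finger_axis_info or infer_finger_axis(skeleton)
    box = collection_box(skeleton.shape, axis, cfg)
    r0, r1, c0, c1 = box
    center = ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)

    # Harris on the full skeleton (restricting first would create
    # artificial line endpoints at the box boundary), candidates kept on
    # the skeleton inside the box
    response = harris_response(skeleton.astype(float), k=cfg.harris_k,
                               sigma=cfg.harris_sigma)
    keep = np.zeros_like(skeleton)
    keep[r0:r1, c0:c1] = skeleton[r0:r1, c0:c1]
    response = np.where(keep, response, 0.0)
    corners = detect_corners(response, threshold_frac=cfg.threshold_frac,
                             nms_radius=cfg.nms_radius)
    inside = [
        (i, tuple(pt)) for i, pt in enumerate(corners.points)
        if r0 <= pt[0] < r1 and c0 <= pt[1] < c1
    ]
    if inside:
        def key(item):
            i, (r, c) = item
            dist = math.hypot(r - center[0], c - center[1])
            return (dist, -corners.responses[i], r, c)

        _, best = min(inside, key=key)
        return SamplingPoint(point=(int(best[0]), int(best[1])), box=box,
                             fallback=False, corners=corners)

    # fallback: nearest skeleton pixel to the box center (box first,
    # whole image if the box holds no skeleton at all)
    rows, cols = np.nonzero(keep)
    if len(rows) == 0:
        rows, cols = np.nonzero(skeleton)
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    i = int(np.argmin(d2))
    return SamplingPoint(point=(int(rows[i]), int(cols[i])), box=box,
                         fallback=True, corners=corners)
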