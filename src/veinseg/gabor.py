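"""Adaptive Gabor filter bank for near-infrared finger-vein images.

The local window width of the Gabor transform is set block-by-block from
the image's *differential excitation* — the mean, over a block, of the
per-pixel ratio of gradient magnitude to intensity (a Weber-law local
change measure).  Each 16x16-pixel block then receives a 5-scale x
8-orientation complex Gabor bank whose widths are the block width plus
steps of +-2, with sigma = W/2 and omega = 2*pi/W tied to the window
width W.  Filtering a block with its own bank, in context, yields a
40-channel magnitude feature stack for the whole image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .config import GaborConfig

__all__ = [
    "PadRecord", "BlockGrid", "GaborBank", "extract_roi_and_pad",
    "compute_gradients", "adaptive_window_width", "build_gabor_bank",
    "gabor_kernel", "compute_block_grid", "filter_image",
]

# 3x3 gradient operator pairs (x = columns increasing rightward,
# y = rows increasing downward)
_OPERATORS = {
    "sobel": (
        np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float),
        np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float),
    ),
    "prewitt": (
        np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float),
        np.array([[-1, -1, -1], [0, 0, 0], [1, 1, 1]], dtype=float),
    ),
}


@dataclass(frozen=True)
class PadRecord:
    """Bookkeeping for mapping padded-frame coordinates back to the original.

    ``crop`` is the half-open (row0, row1, col0, col1) window taken from the
    original image; ``offset`` is the (row, col) position of that window's
    top-left corner inside the padded square.
    """

    original_shape: tuple[int, int]
    crop: tuple[int, int, int, int]
    offset: tuple[int, int]
    target_size: int

    @property
    def content_slices(self) -> tuple[slice, slice]:
        """Slices of the padded image holding actual image content."""
        r0, r1, c0, c1 = self.crop
        orow, ocol = self.offset
        return (slice(orow, orow + (r1 - r0)), slice(ocol, ocol + (c1 - c0)))

    def to_original(self, row: int, col: int) -> tuple[int, int]:
        """Map a padded-frame pixel to original-image coordinates."""
        r0, _, c0, _ = self.crop
        return (row - self.offset[0] + r0, col - self.offset[1] + c0)


@dataclass(frozen=True)
class BlockGrid:
    """Per-block adaptive central window widths over a tiled image."""

    block_size: int
    widths: np.ndarray          # (block_rows, block_cols) float, clamped
    image_shape: tuple[int, int]

    @property
    def block_rows(self) -> int:
        return self.widths.shape[0]

    @property
    def block_cols(self) -> int:
        return self.widths.shape[1]


@dataclass(frozen=True)
class GaborBank:
    """A 5-scale x 8-orientation complex Gabor filter set.

    Every filter obeys sigma = W/2 and omega = 2*pi/W where W is its
    window width; the five widths are the (clamped) center width plus
    steps of +-``scale_step``.
    """

    center_width: float
    widths: tuple[float, ...]
    orientations: tuple[float, ...]
    truncate_sigmas: float = 3.0
    _kernels: dict = field(default_factory=dict, repr=False, compare=False)

    def sigma(self, scale: int) -> float:
        return self.widths[scale] / 2.0

    def omega(self, scale: int) -> float:
        return 2.0 * math.pi / self.widths[scale]

    def kernel(self, scale: int, orientation: int) -> np.ndarray:
        key = (scale, orientation)
        if key not in self._kernels:
            self._kernels[key] = gabor_kernel(
                self.widths[scale], self.orientations[orientation],
                truncate=self.truncate_sigmas)
        return self._kernels[key]


def extract_roi_and_pad(
    image: np.ndarray, target_size: int = 256,
) -> tuple[np.ndarray, PadRecord]:
    """Crop the image to its finger region and zero-pad to a square.

    Images no larger than ``target_size`` in both dimensions are kept
    whole; larger frames (e.g. 640x480 acquisitions with the bright
    finger on a dark background) are first cropped to the bounding box
    of the bright region.  The content is centered in a
    ``target_size`` x ``target_size`` canvas padded with zeros, and a
    :class:`PadRecord` maps coordinates back.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    h, w = image.shape
    if h <= target_size and w <= target_size:
        r0, r1, c0, c1 = 0, h, 0, w
    else:
        r0, r1, c0, c1 = _finger_bounding_box(image)
    ch, cw = r1 - r0, c1 - c0
    if ch > target_size or cw > target_size:
        raise ValueError(
            f"ROI of size {ch}x{cw} exceeds target size "
            f"{target_size}x{target_size}")
    cropped = image[r0:r1, c0:c1]
    out = np.zeros((target_size, target_size), dtype=float)
    orow = (target_size - ch) // 2
    ocol = (target_size - cw) // 2
    out[orow:orow + ch, ocol:ocol + cw] = cropped
    rec = PadRecord(original_shape=(h, w), crop=(r0, r1, c0, c1),
                    offset=(orow, ocol), target_size=target_size)
    return out, rec


def _finger_bounding_box(image: np.ndarray) -> tuple[int, int, int, int]:
    """Bounding box of the brightest (finger) region, Otsu + largest blob."""
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    thr = threshold_otsu(image)
    bright = image > thr
    lab = label(bright)
    if lab.max() == 0:
        return 0, image.shape[0], 0, image.shape[1]
    regions = regionprops(lab)
    best = max(regions, key=lambda r: r.area)
    r0, c0, r1, c1 = best.bbox
    return r0, r1, c0, c1


def compute_gradients(
    block: np.ndarray, operator: str = "sobel",
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal/vertical gradient components by 3x3 convolution.

    Borders are handled by reflection; the operator pair is Sobel by
    default (Prewitt available).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or min(block.shape) < 3:
        raise ValueError(
            f"block of shape {block.shape} is smaller than the 3x3 "
            "gradient operator support")
    wx, wy = _OPERATORS[operator]
    gx = ndimage.convolve(block, wx, mode="reflect")
    gy = ndimage.convolve(block, wy, mode="reflect")
    return gx, gy


def adaptive_window_width(
    block: np.ndarray,
    w_min: float = 6.0,
    w_max: float = 32.0,
    operator: str = "sobel",
    eps: float = 1.0,
) -> float:
    """Central Gabor window width from a block's differential excitation.

    The per-pixel excitation is sqrt(gx^2+gy^2)/max(P, eps) — gradient
    magnitude over intensity — averaged over the block and clamped to
    [w_min, w_max].  The ratio form makes the width invariant to global
    intensity scaling.
    """
    block = np.asarray(block, dtype=float)
    if block.size == 0:
        raise ValueError("empty block")
    if min(block.shape) < 3:
        return float(w_min)
    gx, gy = compute_gradients(block, operator=operator)
    excitation = np.hypot(gx, gy) / np.maximum(block, eps)
    raw = float(excitation.mean())
    return float(min(max(raw, w_min), w_max))


def build_gabor_bank(
    center_width: float, config: GaborConfig | None = None,
) -> GaborBank:
    """Bank of ``n_scales`` widths stepped by ``scale_step`` around the center.

    The center is clamped so that every scale width stays inside
    [w_min, w_max]; orientations are theta_k = k*pi/n for k = 0..n-1.
    """
    cfg = config or GaborConfig()
    half = cfg.n_scales // 2
    lo = cfg.w_min + half * cfg.scale_step
    hi = cfg.w_max - half * cfg.scale_step
    center = float(min(max(center_width, lo), hi))
    widths = tuple(center + cfg.scale_step * (k - half)
                   for k in range(cfg.n_scales))
    thetas = tuple(k * math.pi / cfg.n_orientations
                   for k in range(cfg.n_orientations))
    return GaborBank(center_width=center, widths=widths, orientations=thetas,
                     truncate_sigmas=cfg.truncate_sigmas)


def gabor_kernel(width: float, theta: float, truncate: float = 3.0,
                 amplitude: float = 1.0) -> np.ndarray:
    """Complex Gabor kernel with window width ``width`` and direction ``theta``.

    g(x, y) = (l / 2 pi sigma^2) * exp(-(u^2+v^2)/(2 sigma^2))
              * (exp(j omega u) - c),
    with u, v the coordinates rotated by theta, sigma = W/2 and
    omega = 2 pi / W.  The constant c removes the DC component of the
    real part; it is evaluated on the sampled, truncated grid (where it
    coincides with the continuous value exp(-omega^2 sigma^2 / 2) up to
    truncation error) so the cancellation is exact.
    """
    if width < 2:
        raise ValueError(f"window width {width} must be >= 2")
    sigma = width / 2.0
    omega = 2.0 * math.pi / width
    half = int(math.ceil(truncate * sigma))
    coords = np.arange(-half, half + 1, dtype=float)
    x, y = np.meshgrid(coords, coords)          # x: columns, y: rows
    u = x * math.cos(theta) + y * math.sin(theta)
    v = -x * math.sin(theta) + y * math.cos(theta)
    envelope = np.exp(-(u * u + v * v) / (2.0 * sigma * sigma))
    carrier = np.exp(1j * omega * u)
    dc = float((envelope * carrier.real).sum() / envelope.sum())
    norm = amplitude / (2.0 * math.pi * sigma * sigma)
    return norm * envelope * (carrier - dc)


def compute_block_grid(
    image: np.ndarray, config: GaborConfig | None = None,
) -> BlockGrid:
    """Tile the padded image and estimate each block's window width."""
    cfg = config or GaborConfig()
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    bs = cfg.block_size
    if h % bs or w % bs:
        raise ValueError(
            f"image shape {image.shape} is not a multiple of block size {bs}")
    rows, cols = h // bs, w // bs
    widths = np.empty((rows, cols), dtype=float)
    for i in range(rows):
        for j in range(cols):
            block = image[i * bs:(i + 1) * bs, j * bs:(j + 1) * bs]
            widths[i, j] = adaptive_window_width(
                block, w_min=cfg.w_min, w_max=cfg.w_max,
                operator=cfg.gradient_operator)
    return BlockGrid(block_size=bs, widths=widths, image_shape=(h, w))


def _filter_full_image(image: np.ndarray, width: float, theta: float,
                       truncate: float) -> np.ndarray:
    """Magnitude of the full-image complex Gabor response, reflect borders."""
    kernel = gabor_kernel(width, theta, truncate=truncate)
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="reflect")
    resp = signal.fftconvolve(padded, kernel, mode="same")
    resp = resp[half:half + image.shape[0], half:half + image.shape[1]]
    return np.abs(resp)


def filter_image(
    image: np.ndarray,
    grid: BlockGrid,
    config: GaborConfig | None = None,
) -> np.ndarray:
    """Per-block adaptive Gabor filtering of the whole image.

    Returns the (rows, cols, n_scales, n_orientations) stack of complex
    response magnitudes.  Each block is filtered with its own bank using
    the full surrounding image as context (equivalent to filtering the
    whole image with that bank and keeping the block), so tile seams
    introduce no artifacts.  Widths are rounded to the nearest integer
    so full-image responses can be shared between blocks.
    """
    cfg = config or GaborConfig()
    image = np.asarray(image, dtype=float)
    if grid.image_shape != image.shape:
        raise ValueError(
            f"grid was built for shape {grid.image_shape}, "
            f"got image of shape {image.shape}")
    bs = grid.block_size
    half_scales = cfg.n_scales // 2
    thetas = [k * math.pi / cfg.n_orientations
              for k in range(cfg.n_orientations)]

    # integer scale widths per block, via the clamped bank construction
    bank_widths = np.empty(grid.widths.shape + (cfg.n_scales,), dtype=int)
    lo = cfg.w_min + half_scales * cfg.scale_step
    hi = cfg.w_max - half_scales * cfg.scale_step
    centers = np.clip(np.rint(grid.widths), lo, hi)
    for s in range(cfg.n_scales):
        bank_widths[..., s] = centers + cfg.scale_step * (s - half_scales)

    stack = np.empty(image.shape + (cfg.n_scales, cfg.n_orientations))
    cache: dict[tuple[int, int], np.ndarray] = {}
    for i in range(grid.block_rows):
        rsl = slice(i * bs, (i + 1) * bs)
        for j in range(grid.block_cols):
            csl = slice(j * bs, (j + 1) * bs)
            for s in range(cfg.n_scales):
                wdt = int(bank_widths[i, j, s])
                for o, theta in enumerate(thetas):
                    key = (wdt, o)
                    if key not in cache:
                        cache[key] = _filter_full_image(
                            image, wdt, theta, cfg.truncate_sigmas)
                    stack[rsl, csl, s, o] = cache[key][rsl, csl]
    return stack
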