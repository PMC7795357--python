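"""Synthetic near-infrared finger-vein image generator.

Produces images emulating NIR transmission/reflection acquisitions: a
bright, smoothly varying tissue background carrying dark curvilinear
veins (smooth random spline paths, optionally branching at planted
junctions), Gaussian-blurred to soft edges and corrupted by additive
Gaussian noise.  Every sample ships its ground-truth mask, one-pixel
centerlines, and junction coordinates, so each pipeline stage can be
tested without external databases.  Deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SyntheticSample", "generate", "generate_suite", "NOISE_LEVELS"]

# graded difficulty: additive noise standard deviation in gray levels
NOISE_LEVELS = {"low": 2.0, "moderate": 10.0, "high": 25.0}


@dataclass
class SyntheticSample:
    """A synthetic NIR finger image with full ground truth."""

    image: np.ndarray            # uint8, [0, 255]
    truth_mask: np.ndarray       # bool vein mask
    centerlines: np.ndarray      # bool one-pixel vein centerlines
    junctions: list[tuple[int, int]]
    params: dict = field(default_factory=dict)


def _smooth_curve(rng, p0, p1, shape, jitter=6.0, n_waypoints=4):
    """Pixel chain of a smooth random curve from p0 to p1 (spline path)."""
    from scipy.interpolate import splev, splprep
    from skimage.draw import line

    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    t = np.linspace(0, 1, n_waypoints + 2)
    pts = p0[None] + t[:, None] * (p1 - p0)[None]
    pts[1:-1] += rng.normal(0, jitter, size=(n_waypoints, 2))
    k = min(3, len(pts) - 1)
    tck, _ = splprep(pts.T, s=0, k=k)
    dense = np.asarray(splev(np.linspace(0, 1, 8 * len(pts)), tck)).T
    dense = np.clip(np.rint(dense), 0,
                    np.array(shape, dtype=float) - 1).astype(int)
    chain: list[tuple[int, int]] = []
    for (r0, c0), (r1, c1) in zip(dense[:-1], dense[1:]):
        rr, cc = line(r0, c0, r1, c1)
        for r, c in zip(rr, cc):
            if not chain or chain[-1] != (r, c):
                chain.append((int(r), int(c)))
    return chain


def generate(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    n_veins: int = 3,
    width_range: tuple[int, int] = (10, 20),
    contrast: float = 60.0,
    noise_sigma: float = 2.0,
    background_range: tuple[float, float] = (140.0, 200.0),
    n_branches: int = 1,
    margin: int = 16,
    finger_frame: bool = False,
    junction_region: tuple[int, int, int, int] | None = None,
) -> SyntheticSample:
    """Render one synthetic vein image with ground truth.

    Veins run along the (vertical) finger axis, one per horizontal
    strip so independent veins do not cross; ``n_branches`` side
    branches are planted, each creating one recorded junction
    (optionally constrained to lie inside ``junction_region``).
    ``finger_frame=True`` renders a bright finger silhouette on a dark
    border (the raw-acquisition scenario needing an ROI crop);
    otherwise the whole canvas is tissue.

    ``contrast`` is the gray-level depth of the veins below the local
    background; 0 yields a mask with no visible veins.
    """
    from skimage.draw import disk as draw_disk
    from skimage.morphology import dilation, disk

    h, w = shape
    widths = tuple(int(v) for v in width_range)
    if widths[0] < 3 or widths[1] >= min(h, w) // 2:
        raise ValueError(
            f"vein widths {width_range} impossible on a {h}x{w} canvas")
    if n_veins < 1:
        raise ValueError("need at least one vein")
    rng = np.random.default_rng(seed)

    # tissue region (whole canvas, or a bright capsule on a dark border)
    if finger_frame:
        # finger silhouette sized so its ROI fits the 256x256 working frame
        tissue = np.zeros(shape, dtype=bool)
        fh, fw = min(int(0.85 * h), 248), min(int(0.45 * w), 180)
        r0, c0 = (h - fh) // 2, (w - fw) // 2
        tissue[r0:r0 + fh, c0:c0 + fw] = True
        rad = fw // 2
        for rc in (r0 + rad, r0 + fh - rad):
            rr, cc = draw_disk((rc, c0 + fw // 2), rad, shape=shape)
            tissue[rr, cc] = True
        top, bottom = r0 + margin, r0 + fh - margin
        left, right = c0 + margin, c0 + fw - margin
    else:
        tissue = np.ones(shape, dtype=bool)
        # veins span the full height (they continue beyond the ROI, as in
        # a real acquisition) so no artificial endpoints appear in-frame
        top, bottom = 0, h
        left, right = margin, w - margin

    # one vein per vertical strip, so primary veins never cross
    strip = (right - left) / n_veins
    centerlines = np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    paths = []
    radii = []
    for i in range(n_veins):
        lo = left + i * strip
        hi = left + (i + 1) * strip
        jitter = min(6.0, strip / 4.0)
        p0 = (top, rng.uniform(lo + strip / 4, hi - strip / 4))
        p1 = (bottom, rng.uniform(lo + strip / 4, hi - strip / 4))
        chain = _smooth_curve(rng, p0, p1, shape, jitter=jitter)
        paths.append(chain)
        radii.append(max(1, int(rng.integers(widths[0], widths[1] + 1)) // 2))

    junctions: list[tuple[int, int]] = []
    for _ in range(n_branches):
        if junction_region is not None:
            jr0, jr1, jc0, jc1 = junction_region
            candidates = [
                (i, [p for p in paths[i]
                     if jr0 <= p[0] < jr1 and jc0 <= p[1] < jc1])
                for i in range(n_veins)
            ]
            candidates = [(i, pts) for i, pts in candidates if pts]
            if candidates:
                parent, inside = candidates[int(rng.integers(len(candidates)))]
                anchor = inside[len(inside) // 2]
            else:
                parent = int(rng.integers(n_veins))
                anchor = paths[parent][
                    int(rng.uniform(0.3, 0.7) * len(paths[parent]))]
        else:
            parent = int(rng.integers(n_veins))
            anchor = paths[parent][
                int(rng.uniform(0.3, 0.7) * len(paths[parent]))]
        length = rng.uniform(0.2, 0.35) * h
        angle = rng.uniform(0.35, 0.75) * np.pi * rng.choice([-1, 1])
        end = (min(bottom - 1, anchor[0] + length * abs(np.cos(angle))),
               float(np.clip(anchor[1] + length * np.sin(angle),
                             left, right - 1)))
        branch = _smooth_curve(rng, anchor, end, shape, jitter=3.0,
                               n_waypoints=2)
        paths.append(branch)
        radii.append(max(1, widths[0] // 2))
        # the recorded junction is the rendered bifurcation: the last
        # branch pixel still 8-adjacent to the parent path (a spline may
        # hug its parent for a few pixels before separating)
        parent_set = set(paths[parent])
        junction = anchor
        for p in branch:
            if any((p[0] + dr, p[1] + dc) in parent_set
                   for dr in (-1, 0, 1) for dc in (-1, 0, 1)):
                junction = p
            else:
                break
        junctions.append(junction)

    for chain, rad in zip(paths, radii):
        line_img = np.zeros(shape, dtype=bool)
        rr = [p[0] for p in chain]
        cc = [p[1] for p in chain]
        line_img[rr, cc] = True
        line_img &= tissue
        centerlines |= line_img
        mask |= dilation(line_img, disk(rad))
    mask &= tissue

    # smooth low-frequency background, veins carved `contrast` levels deep
    lo_bg, hi_bg = background_range
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=min(h, w) / 8)
    span = field_.max() - field_.min()
    background = lo_bg + (field_ - field_.min()) / (span or 1.0) * (hi_bg - lo_bg)
    image = np.where(tissue, background, 18.0)
    image = image - contrast * gaussian_filter(mask.astype(float), 1.0)
    image = image + rng.normal(0, noise_sigma, size=shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return SyntheticSample(
        image=image, truth_mask=mask, centerlines=centerlines,
        junctions=[(int(r), int(c)) for r, c in junctions],
        params={
            "seed": int(seed), "shape": list(shape), "n_veins": n_veins,
            "width_range": list(widths), "contrast": contrast,
            "noise_sigma": noise_sigma,
            "background_range": list(background_range),
            "n_branches": n_branches, "finger_frame": finger_frame,
        },
    )


def generate_suite(
    n_images: int,
    difficulty_levels: tuple[str, ...] = ("low", "moderate"),
    seed: int = 0,
    **kwargs,
) -> list[SyntheticSample]:
    """Reproducible graded test suite: ``n_images`` samples per noise level.

    Difficulty names map to additive-noise standard deviations via
    :data:`NOISE_LEVELS` (low: 2, moderate: 10, high: 25 gray levels);
    each sample's ``params['difficulty']`` records its level.
    """
    if n_images < 1:
        raise ValueError("need at least one image per level")
    rng = np.random.default_rng(seed)
    samples = []
    for level in difficulty_levels:
        sigma = NOISE_LEVELS[level]
        for _ in range(n_images):
            sub_seed = int(rng.integers(2**31))
            s = generate(seed=sub_seed, noise_sigma=sigma, **kwargs)
            s.params["difficulty"] = level
            samples.append(s)
    return samples
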