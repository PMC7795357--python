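"""LBP-style fusion of multi-orientation Gabor magnitudes.

At each pixel and scale the eight orientation magnitudes are thresholded
against their own mean: orientations strictly above the mean contribute
a set bit, ties and below-mean responses contribute 0.  The eight bits
are packed into one decimal code in [0, 255] per scale, collapsing the
40-channel Gabor stack to five fused feature images.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fuse_orientations"]


def fuse_orientations(stack: np.ndarray, lsb_first: bool = True) -> np.ndarray:
    """Fuse the orientation axis of a Gabor feature stack into 8-bit codes.

    Parameters
    ----------
    stack
        Array of shape (..., n_scales, 8): non-negative response
        magnitudes with the orientation axis last.
    lsb_first
        Orientation index s (1-based) maps to bit weight 2**(s-1); the
        first orientation is the least-significant bit.

    Returns
    -------
    Integer code array of shape (..., n_scales), values in [0, 255].
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[-1] != 8:
        raise ValueError(
            f"expected 8 orientation channels, got {stack.shape[-1]}")
    avg = stack.mean(axis=-1, keepdims=True)
    bits = stack - avg > 0           # strict: ties map to 0
    weights = 1 << np.arange(8)
    if not lsb_first:
        weights = weights[::-1]
    codes = (bits * weights).sum(axis=-1)
    return codes.astype(np.uint8)
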