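"""Locate the blood-sampling point on a vein network with a junction.

Builds a synthetic sample whose vein network branches inside the distal
100x200 collection box, detects Harris corners (vein junctions) on the
one-pixel vein skeleton and picks the corner nearest the box center —
the point where lancing yields the most blood.  On a segmented mask the
same skeleton would come from ``thin_mask(mask)``; note that thinning a
20-pixel-wide vein can shift the bifurcation by several pixels relative
to the drawn centerline, so ground-truth comparisons here use the
generator's own centerlines.
"""

import math

from veinseg import FingerAxis, generate, locate_sampling_point

sample = generate(seed=1009, noise_sigma=2.0, n_branches=1,
                  junction_region=(20, 80, 48, 208))
skeleton = sample.centerlines
point = locate_sampling_point(skeleton, FingerAxis("vertical", "start"))

jr, jc = sample.junctions[0]
dist = math.hypot(point.point[0] - jr, point.point[1] - jc)
print(f"planted junction      : {(jr, jc)}")
print(f"collection box (r,c)  : rows {point.box[0]}..{point.box[1]}, "
      f"cols {point.box[2]}..{point.box[3]}")
print(f"sampling point (r, c) : {point.point}")
print(f"distance to junction  : {dist:.1f} px")
print(f"fallback used         : {point.fallback}")
print(f"corners detected      : {len(point.corners)}")

# The sampling point sits on the skeleton within a couple of pixels of
# the planted bifurcation; fallback=True would mean no corner exceeded
# the Harris threshold inside the box and the nearest skeleton pixel to
# the box center was returned instead.
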