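"""Segment a synthetic NIR finger-vein image and score it against truth.

Generates one 256x256 synthetic sample (dark curvilinear veins on a
smooth bright background, additive noise sigma = 2 gray levels), runs
the full adaptive-Gabor / LBP-fusion / GMM graph-cut pipeline, and
prints the energy trace, the foreground/background relative-entropy
trace, and the overlap with the known vein mask.
"""

from veinseg import RunConfig, generate, jaccard, mean_bias_error, segment

sample = generate(seed=3, noise_sigma=2.0)
result = segment(sample.image, RunConfig(), seed=1)

print(f"iterations run      : {result.iterations}")
print(f"converged (|dKL|<tol): {result.converged}")
print("energy trace        :", [round(e) for e in result.energy_trace])
print("KL(fg||bg) trace    :", [round(k, 2) for k in result.kl_trace])
print(f"Jaccard similarity  : {jaccard(sample.truth_mask, result.labels):.3f}")
print(f"mean bias error     : "
      f"{mean_bias_error(sample.truth_mask, result.labels):+.3f}")

# The energy decreases monotonically (each graph cut is a global optimum
# for the current mixtures) while the fg/bg relative entropy grows as the
# two mixture models specialize.  JS measures mask overlap in [0, 1]; a
# negative MBE means the predicted vein region is larger than the truth —
# expected here, because Gabor responses extend beyond the vein borders.
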