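"""Deconvolve PCR stutter from a fragment-length peak profile.

Builds a stutter model for a 16-base A-repeat, forward-convolves a known
allele mixture (60% wild type, 40% one-base deletion) into a noisy peak
profile, and recovers the true allele fractions by bounded least squares.
"""

import numpy as np

from msiedit import (
    CmsLocus,
    PeakProfile,
    StutterModel,
    build_contribution_matrix,
    call_mutation_status,
    classify_frames,
    deconvolve,
    simulate_peak_profile,
    stutter_shape,
)

locus = CmsLocus("TGFBR2", "TGFBR2", "A", repeat_length=16, wt_fragment_length=120)
model = StutterModel(slope=0.35, midpoint=18.0,
                     reference_stutter={"TGFBR2": stutter_shape(0.62)})
matrix = build_contribution_matrix(locus, model)

truth = np.zeros(9)
truth[4], truth[3] = 0.6, 0.4  # 60% wild type, 40% m1 (one-base deletion)
profile = simulate_peak_profile(truth, matrix, noise_cv=0.03, seed=1, intensity=9000)

print("observed band fractions (offsets -4..+4):")
print("  ", np.round(profile.normalized(), 3))

dist = deconvolve(profile, matrix)
print("deconvolved allele fractions:")
print("  ", np.round(dist.fractions, 3), f"(residual {dist.residual_norm:.4f})")

frames = classify_frames(dist)
call = call_mutation_status(dist)
print(f"mutant fraction {dist.mutant_fraction:.3f} -> status {call.status}, "
      f"dominant frame {call.dominant_frame}")
print(f"frame shares: M0 {frames.m0_fraction:.3f}  M1 {frames.m1_fraction:.3f}  "
      f"M2 {frames.m2_fraction:.3f}")
# The observed profile smears ~40% of its mass into stutter bands; the
# deconvolution concentrates it back onto the two true alleles, so the
# recovered fractions should read ~0.60/0.40 and the call "mutant"/M1.
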