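"""Regional (AHA 16-segment) volume-time curves from a contour stack.

Slices are grouped into basal/mid/apical layers and each endocardial contour
is split into 60-degree (basal, mid) or 90-degree (apical) sectors about its
centroid.  For the rotationally symmetric phantom every segment of a layer
carries the same share of that layer's volume, which the printout makes
visible at end diastole and end systole.
"""

import numpy as np

from cinevol import PhantomSpec, analyze_study, generate_phantom

study, truth = generate_phantom(PhantomSpec(noise_sd_mm=0.2, seed=7))
curve, idx = analyze_study(study)

ed = int(np.argmax(curve.global_volumes))
es = int(np.argmin(curve.global_volumes))
print(f"global volume: ED {curve.global_volumes[ed]:.2f} ml (phase {ed}), "
      f"ES {curve.global_volumes[es]:.2f} ml (phase {es})")
print()
print(f"{'segment':>8}{'layer':>8}{'ED (ml)':>10}{'ES (ml)':>10}")
layers = ["basal"] * 6 + ["mid"] * 6 + ["apical"] * 4
for k in range(16):
    print(f"{k + 1:>8}{layers[k]:>8}{curve.segment_volumes[k, ed]:>10.3f}"
          f"{curve.segment_volumes[k, es]:>10.3f}")

seg_sum = curve.segment_volumes.sum(axis=0)
print()
print(f"conservation: max |sum(segments) - global| / global = "
      f"{np.max(np.abs(seg_sum - curve.global_volumes) / curve.global_volumes):.2e}")
print("Equal values within each layer reflect the phantom's rotational symmetry")
print("(small differences come from the 0.2 mm contour noise).")
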