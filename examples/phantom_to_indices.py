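"""Generate a synthetic cine study and recover the LV function indices.

The phantom is a contracting half-ellipsoid ventricle (EDV 160 ml, EF 40%)
sampled as 10 short-axis slices x 20 phases of circular contours, with the
most basal slice flagged as showing the mitral valve (excluded, as in a real
analysis).  The pipeline integrates the contours by slice summation and
derives EDV, ESV, SV, EF and the time to maximal contraction, which are
printed next to the analytic ground truth of the same (included) slice grid.
"""

from cinevol import PhantomSpec, analyze_study, generate_phantom

spec = PhantomSpec()  # EDV 160 ml, EF 40%, 10 x 8 mm slices, 20 phases
study, truth = generate_phantom(spec)
curve, idx = analyze_study(study)

print(f"{'':>24}{'pipeline':>12}{'truth':>12}")
for label, got, want in [
    ("EDV (ml)", idx.edv_ml, truth.edv_ml),
    ("ESV (ml)", idx.esv_ml, truth.esv_ml),
    ("SV (ml)", idx.sv_ml, truth.sv_ml),
    ("EF (%)", idx.ef_pct, truth.ef_pct),
    ("time to min (% cycle)", idx.time_to_min_pct, truth.time_to_min_pct),
]:
    print(f"{label:>24}{got:>12.3f}{want:>12.3f}")

print()
print("The truth EDV is below the prescribed 160 ml because the basal slice")
print("with the mitral valve is excluded from both the pipeline and the truth;")
print("EF is unaffected since contraction rescales every slice equally.")
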