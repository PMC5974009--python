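# cinevol

Regional and global left-ventricular (LV) volumetry from segmented
short-axis cine MRI contours, plus the method-agreement statistics used to
validate one measurement system against another.

The package addresses the planning stage of computer-assisted cardiac
resynchronisation therapy (CRT): before the intervention, the clinical team
needs the LV function indices — end-diastolic volume (EDV), end-systolic
volume (ESV), stroke volume (SV = EDV − ESV), ejection fraction
(EF = SV/EDV · 100%) — and the regional volume–time curves that expose
mechanical dyssynchrony, computed quickly and automatically from the
segmented cine stack. It is written for researchers building or validating
such analysis pipelines: it operates on contours (ordered planar polygons
per slice, phase and role), not on images; segmentation is upstream.

## Model

The endocardial blood-pool volume at each cardiac phase is the
Simpson-type slice summation

```
EV = Σ_slices ( |area_segment| × slice thickness )
```

evaluated per AHA segment and for the whole contour. Slices showing the
mitral valve, or lying beyond the LV, are excluded; remaining contours are
re-positioned in-plane so the per-phase endocardial centroids fall on a
least-squares straight long-axis line (translation only, volume-neutral).
Slices are divided into basal/mid/apical layers and each contour into
60° (basal, mid) or 90° (apical) sectors about its centroid, counted
counterclockwise from the anterior reference direction — the AHA 16-segment
model (1–6 basal, 7–12 mid, 13–16 apical; the apical cap, segment 17, has
no short-axis blood pool and is excluded). Sector areas come from exact
half-plane polygon clipping, so the 16 segment volumes sum to the global
volume to machine precision. From the global curve follow EDV (maximum),
ESV (minimum), SV, EF and the time to maximal contraction (time of the
minimum as % of the cycle).

For validation the package ships an analytic phantom — a contracting
truncated half-ellipsoid ventricle, V = (2/3)πr²L, with prescribed EDV, EF
and end-systolic timing, optional contour noise and slice misalignment —
whose per-slice, per-segment ground truth is known in closed form, and a
method-agreement module implementing Pearson r with exact p-values, OLS
regression, Bland–Altman bias and 95% limits of agreement (bias ± 1.96 SD
of the paired differences), the coefficient of variation
(SD of differences / pooled mean), the categorical rule
(excellent if r > 0.80 or CoV < 10%; good if r > 0.6; poor otherwise) and
per-subject volume-curve correlation summaries (median, IQR, time-to-minimum
differences).

## Worked example

```sh
python examples/phantom_to_indices.py
```

```
                            pipeline       truth
                EDV (ml)     135.990     135.996
                ESV (ml)      81.594      81.598
                 SV (ml)      54.396      54.398
                  EF (%)      40.000      40.000
   time to min (% cycle)      35.000      35.000
```

The phantom prescribes EDV 160 ml and EF 40% over a 10-slice stack; the
most basal slice shows the mitral valve and is excluded from both pipeline
and truth, which is why the reported EDV is 136 ml — but EF survives the
exclusion exactly, because contraction rescales every slice radius by the
same factor. The pipeline recovers EF to better than 0.001 percentage
points and places end systole at 35% of the cycle, where the phantom put
it. `examples/segment_curves.py` prints the 16 per-segment volumes at end
diastole/systole (equal within each layer, by the phantom's rotational
symmetry), and `examples/method_agreement.py` runs the full agreement
battery between two noisy re-measurements of a 10-subject cohort
(r = 0.9997, bias −0.01 EF points, CoV 0.76% → excellent agreement).

The same workflow is available from the shell:

```sh
cinevol phantom --seed 17 --out study.json --truth truth.json
cinevol analyze study.json --out curves.csv --indices indices.json
cinevol compare a_indices.csv b_indices.csv --curves a_curves/ b_curves/ --out agreement.json
```

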