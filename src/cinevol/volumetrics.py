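"""Slice-summation LV volumetry and derived function indices.

The endocardial blood-pool volume at each cardiac phase is the Simpson-type
slice sum

    EV = sum over slices of |segment area| x slice thickness,

evaluated per AHA segment (areas from the sector clipping in :mod:`.aha`)
and, independently, for the full endocardial polygon to give the global
volume.  Volumes are reported in millilitres (mm^3 / 1000).

Preprocessing mirrors the interventional workflow: slices in which the
mitral valve is visible, and slices beyond the LV, are excluded; remaining
contours are re-positioned in-plane so the per-phase endocardial centroids
lie on a straight long-axis line fitted by least squares (translation only,
which leaves every area — and hence every volume — unchanged).

From the global curve the function indices follow: EDV (curve maximum),
ESV (minimum), SV = EDV - ESV, EF = SV/EDV x 100, and the time to maximal
contraction, i.e. the time of the minimum expressed as a percentage of the
cardiac cycle.
"""

from __future__ import annotations

import numpy as np

from . import aha
from .io import (
    ENDO,
    N_SEGMENTS,
    CineStudy,
    CineTiming,
    Contour,
    FunctionIndices,
    GeometryError,
    SchemaError,
    VolumeCurve,
)

__all__ = [
    "polygon_area",
    "polygon_centroid",
    "exclude_slices",
    "align_slices",
    "segment_volume_curve",
    "function_indices",
    "time_to_max_contraction",
    "analyze_study",
]


def polygon_area(points) -> float:
    """Absolute shoelace area (mm^2) of a closed polygon; orientation-free."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError(f"polygon needs >= 3 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def polygon_centroid(points) -> np.ndarray:
    """Area-weighted centroid of a closed polygon."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError(f"polygon needs >= 3 points, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    w = x * yn - xn * y
    a = 0.5 * float(np.sum(w))
    if a == 0.0:
        raise GeometryError("degenerate polygon: zero area, centroid undefined")
    cx = float(np.sum((x + xn) * w)) / (6.0 * a)
    cy = float(np.sum((y + yn) * w)) / (6.0 * a)
    return np.array([cx, cy])


def exclude_slices(study: CineStudy) -> CineStudy:
    """Drop slices flagged mitral_valve_visible or beyond_lv, with their contours."""
    kept = [s for s in study.slices if s.included]
    if len(kept) < 3:
        raise SchemaError(
            f"only {len(kept)} slices remain after exclusion; need >= 3"
        )
    kept_idx = {s.slice_index for s in kept}
    contours = [c for c in study.contours if c.slice_index in kept_idx]
    return CineStudy(
        subject_id=study.subject_id,
        contours=contours,
        slices=kept,
        timing=study.timing,
        reference_angle_rad=study.reference_angle_rad,
    )


def align_slices(study: CineStudy) -> CineStudy:
    """Correct in-plane slice misalignment by re-positioning contours.

    Per phase, a straight long-axis model is fitted: the endocardial
    centroids (x, y) of all slices are regressed on z by least squares, and
    every slice's contours (endo and epi) are translated so the endocardial
    centroid lands exactly on the fitted line.  Translation-only, so areas
    and volumes are preserved; aligning an already-aligned study is the
    identity up to floating-point rounding.
    """
    cmap = study.contour_map()
    zmap = {s.slice_index: s.z_mm for s in study.slices}
    slice_indices = [s.slice_index for s in study.slices]
    new_contours: list[Contour] = []
    for phase in range(study.timing.n_phases):
        present = [i for i in slice_indices if (i, phase, ENDO) in cmap]
        z = np.array([zmap[i] for i in present])
        cent = np.array([polygon_centroid(cmap[(i, phase, ENDO)].points) for i in present])
        if len(present) >= 2 and np.ptp(z) > 0:
            A = np.column_stack([z, np.ones_like(z)])
            coef, *_ = np.linalg.lstsq(A, cent, rcond=None)
            fitted = A @ coef
        else:  # no long-axis extent: align to the mean centroid
            fitted = np.repeat(cent.mean(axis=0, keepdims=True), len(present), axis=0)
        shift = {i: fitted[k] - cent[k] for k, i in enumerate(present)}
        for c in study.contours:
            if c.phase_index != phase:
                continue
            dv = shift.get(c.slice_index, np.zeros(2))
            new_contours.append(
                Contour(
                    points=c.points + dv,
                    role=c.role,
                    slice_index=c.slice_index,
                    phase_index=c.phase_index,
                )
            )
    return CineStudy(
        subject_id=study.subject_id,
        contours=new_contours,
        slices=list(study.slices),
        timing=study.timing,
        reference_angle_rad=study.reference_angle_rad,
    )


def _slice_weights(study: CineStudy, spacing_mode: str) -> dict[int, float]:
    """Integration weight (mm) per slice: its thickness, or the midplane spacing."""
    ordered = study.included_slices()
    if spacing_mode == "thickness":
        return {s.slice_index: s.thickness_mm for s in ordered}
    if spacing_mode != "z_spacing":
        raise ValueError(f"spacing_mode must be 'thickness' or 'z_spacing', got {spacing_mode!r}")
    z = np.array([s.z_mm for s in ordered])
    if len(z) < 2:
        return {s.slice_index: s.thickness_mm for s in ordered}
    gaps = np.abs(np.diff(z))
    w = np.empty(len(z))
    w[0], w[-1] = gaps[0], gaps[-1]
    if len(z) > 2:
        w[1:-1] = 0.5 * (gaps[:-1] + gaps[1:])
    return {s.slice_index: float(w[k]) for k, s in enumerate(ordered)}


def segment_volume_curve(study: CineStudy, spacing_mode: str = "thickness") -> VolumeCurve:
    """Per-segment and global volume-time curves of an excluded, aligned study.

    One layer assignment (from the slice z-positions, which do not change
    across the cycle) is shared by all phases, so each AHA segment keeps its
    identity throughout the cycle.
    """
    slices = study.included_slices()
    assignment = aha.assign_layers(slices)
    specs = {layer: aha.sector_spec(layer, study.reference_angle_rad) for layer in aha.LAYERS}
    weights = _slice_weights(study, spacing_mode)
    cmap = study.contour_map()
    n_phases = study.timing.n_phases
    seg_vol = np.zeros((N_SEGMENTS, n_phases))
    glob = np.zeros(n_phases)
    for phase in range(n_phases):
        for s in slices:
            key = (s.slice_index, phase, ENDO)
            if key not in cmap:
                raise SchemaError(f"missing contour for slice {s.slice_index}, phase {phase}, role {ENDO}")
            pts = cmap[key].points
            w = weights[s.slice_index]
            try:
                centre = polygon_centroid(pts)
                areas = aha.segment_areas(pts, centre, specs[assignment.layers[s.slice_index]])
            except GeometryError as e:
                raise GeometryError(f"slice {s.slice_index}, phase {phase}: {e}") from e
            for seg, area in areas.items():
                seg_vol[seg - 1, phase] += area * w / 1000.0
            glob[phase] += polygon_area(pts) * w / 1000.0
    return VolumeCurve(segment_volumes=seg_vol, global_volumes=glob)


def _time_to_min_pct(curve: VolumeCurve, timing: CineTiming) -> tuple[int, float]:
    i_min = int(np.argmin(curve.global_volumes))  # earliest on ties
    return i_min, 100.0 * timing.phase_time(i_min) / timing.cycle_duration_ms


def function_indices(curve: VolumeCurve, timing: CineTiming) -> FunctionIndices:
    """EDV, ESV, SV, EF and time-to-minimum-volume from the global curve.

    ESV is the minimum over phases (the volume immediately after
    contraction), EDV the maximum; ties break to the earliest phase.
    """
    g = curve.global_volumes
    if timing.n_phases != curve.n_phases:
        raise SchemaError(f"timing has {timing.n_phases} phases but curve has {curve.n_phases}")
    edv = float(g.max())
    esv = float(g.min())
    if edv <= 0:
        raise SchemaError("EDV must be positive")
    sv = edv - esv
    _, ttm = _time_to_min_pct(curve, timing)
    return FunctionIndices(
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        ef_pct=100.0 * sv / edv,
        time_to_min_pct=ttm,
    )


def time_to_max_contraction(curve: VolumeCurve, timing: CineTiming) -> float:
    """Time of minimal global volume as a percentage of the cardiac cycle."""
    if timing.n_phases != curve.n_phases:
        raise SchemaError(f"timing has {timing.n_phases} phases but curve has {curve.n_phases}")
    return _time_to_min_pct(curve, timing)[1]


def analyze_study(
    study: CineStudy, spacing_mode: str = "thickness"
) -> tuple[VolumeCurve, FunctionIndices]:
    """Full pipeline: exclude flagged slices, align, integrate, derive indices."""
    prepared = align_slices(exclude_slices(study))
    curve = segment_volume_curve(prepared, spacing_mode=spacing_mode)
    return curve, function_indices(curve, study.timing)
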