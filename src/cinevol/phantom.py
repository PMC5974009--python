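"""Synthetic dynamic LV phantom with analytic ground truth.

The phantom emulates a multi-slice short-axis SSFP cine acquisition of the
left ventricle.  The endocardium is a half-ellipsoid of revolution truncated
at the base plane: the long axis L is fixed over the cycle and contraction
is purely radial, so the cavity volume prescribes the equatorial radius

    V(t) = (2/3) pi r(t)^2 L      =>      r(t) = sqrt(3 V(t) / (2 pi L)).

The prescribed volume curve is a smooth raised-cosine between EDV and ESV,
time-warped so the minimum falls at a chosen fraction of the cycle
(``es_fraction``, the end-systolic time).  Each slice carries a circular
endocardial contour whose radius follows the ellipsoid profile at the slice
midplane, plus an epicardial contour offset outward by the wall thickness.
Optional per-slice in-plane misalignment (constant over the cycle, as for
breath-hold misregistration) and per-vertex radial noise are drawn from a
single seeded generator with a fixed draw order, so generation is fully
reproducible.

The returned :class:`PhantomTruth` carries the analytic volumes evaluated by
the midpoint rule on the same slice grid as the generated stack, with the
same basal slices excluded (mitral valve visible), so pipeline-vs-truth
comparisons are free of discretization mismatch; the continuum value is
available separately via :func:`analytic_volume`.  Because contraction only
rescales the radius, the truth EF equals the prescribed EF exactly for any
slice grid.  Truth segment volumes split each slice by rotational symmetry:
1/6 of the slice volume per basal or mid sector, 1/4 per apical sector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aha
from .io import (
    ENDO,
    EPI,
    N_SEGMENTS,
    CineStudy,
    CineTiming,
    Contour,
    FunctionIndices,
    SliceGeometry,
)

__all__ = ["PhantomSpec", "PhantomTruth", "prescribed_volume", "analytic_volume", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cine acquisition.

    Defaults describe a dilated ventricle typical of a CRT candidate cohort
    imaged with a standard SA cine protocol: EDV 160 ml, EF 40%, 90 mm long
    axis, a 10-slice stack of 8 mm slices, 20 phases over a 1000 ms cycle
    with end systole at 35% of the cycle, and one basal slice in which the
    mitral valve is visible.
    """

    edv_ml: float = 160.0
    ef_pct: float = 40.0
    long_axis_mm: float = 90.0
    wall_thickness_mm: float = 10.0
    n_slices: int = 10
    slice_thickness_mm: float = 8.0
    n_phases: int = 20
    cycle_duration_ms: float = 1000.0
    es_fraction: float = 0.35
    n_vertices: int = 400
    noise_sd_mm: float = 0.0
    misalignment_sd_mm: float = 0.0
    n_mitral_slices: int = 1
    seed: int = 17
    reference_angle_rad: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ef_pct < 100.0:
            raise ValueError(f"ef_pct must be in (0, 100), got {self.ef_pct}")
        if not 0.0 < self.es_fraction < 1.0:
            raise ValueError(f"es_fraction must be in (0, 1), got {self.es_fraction}")
        if self.n_slices < 3:
            raise ValueError(f"n_slices must be >= 3, got {self.n_slices}")
        if self.n_slices * self.slice_thickness_mm > self.long_axis_mm + 1e-9:
            raise ValueError("stack extent n_slices * slice_thickness_mm must not exceed long_axis_mm")
        if self.n_vertices < 16:
            raise ValueError(f"n_vertices must be >= 16, got {self.n_vertices}")
        if self.n_phases < 2:
            raise ValueError(f"n_phases must be >= 2, got {self.n_phases}")
        if not 0 <= self.n_mitral_slices < self.n_slices:
            raise ValueError("n_mitral_slices must be in [0, n_slices)")

    @property
    def esv_ml(self) -> float:
        return self.edv_ml * (1.0 - self.ef_pct / 100.0)


@dataclass(eq=False)
class PhantomTruth:
    """Analytic ground truth on the included-slice grid of a generated phantom."""

    volume_curve_ml: np.ndarray
    segment_volumes_ml: np.ndarray
    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    time_to_min_pct: float

    def indices(self) -> FunctionIndices:
        return FunctionIndices(
            edv_ml=self.edv_ml,
            esv_ml=self.esv_ml,
            sv_ml=self.sv_ml,
            ef_pct=self.ef_pct,
            time_to_min_pct=self.time_to_min_pct,
        )


def prescribed_volume(spec: PhantomSpec, phase_index: int) -> float:
    """Prescribed cavity volume (ml) at one phase of the cycle.

    V(t) = ESV + (EDV - ESV) (1 + cos 2 pi w(t)) / 2 with t the phase time as
    a fraction of the cycle and w a piecewise-linear warp placing the
    minimum at ``es_fraction``: systole (t <= es_fraction) covers the first
    half-period of the cosine, diastole the second.
    """
    if not 0 <= phase_index < spec.n_phases:
        raise IndexError(f"phase_index {phase_index} out of range [0, {spec.n_phases})")
    t = phase_index / spec.n_phases
    if t <= spec.es_fraction:
        w = t / (2.0 * spec.es_fraction)
    else:
        w = (t - spec.es_fraction) / (2.0 * (1.0 - spec.es_fraction)) + 0.5
    esv = spec.esv_ml
    return esv + (spec.edv_ml - esv) * (1.0 + np.cos(2.0 * np.pi * w)) / 2.0


def analytic_volume(r: float, L: float) -> float:
    """Continuum half-ellipsoid volume (ml) for equatorial radius r and length L (mm)."""
    if r <= 0 or L <= 0:
        raise ValueError(f"r and L must be positive, got r={r}, L={L}")
    return (2.0 / 3.0) * np.pi * r * r * L / 1000.0


def _equatorial_radius(v_ml: float, L: float) -> float:
    return float(np.sqrt(3.0 * v_ml * 1000.0 / (2.0 * np.pi * L)))


def generate_phantom(spec: PhantomSpec) -> tuple[CineStudy, PhantomTruth]:
    """Generate a cine contour stack and its analytic ground truth.

    The stack hangs from the base plane: slice k (k = 0 most basal) has its
    midplane at distance (k + 1/2) x slice thickness below the base, i.e. at
    z_k = L - (k + 1/2) x thickness above the apex (z decreases toward the
    apex).  The slice radius follows the ellipsoid profile
    r_k(t) = r(t) sqrt(1 - (d_k / L)^2) with d_k the midplane depth below
    the base, which tapers to zero at the apex.  The top ``n_mitral_slices``
    are flagged mitral_valve_visible; the truth curve is the midpoint-rule
    slice sum over the remaining (included) slices.
    """
    L = spec.long_axis_mm
    th = spec.slice_thickness_mm
    nv = spec.n_vertices
    rng = np.random.default_rng(spec.seed)
    # fixed draw order: per-slice offsets first, then noise per vertex, phase-major
    offsets = rng.normal(0.0, 1.0, (spec.n_slices, 2)) * spec.misalignment_sd_mm

    slices = [
        SliceGeometry(
            slice_index=k,
            z_mm=L - (k + 0.5) * th,
            thickness_mm=th,
            mitral_valve_visible=k < spec.n_mitral_slices,
        )
        for k in range(spec.n_slices)
    ]
    depth = np.array([(k + 0.5) * th for k in range(spec.n_slices)])  # below base
    profile = np.sqrt(np.clip(1.0 - (depth / L) ** 2, 0.0, None))
    angles = 2.0 * np.pi * np.arange(nv) / nv
    ca, sa = np.cos(angles), np.sin(angles)

    volumes = np.array([prescribed_volume(spec, p) for p in range(spec.n_phases)])
    contours: list[Contour] = []
    for phase in range(spec.n_phases):
        r_eq = _equatorial_radius(volumes[phase], L)
        for k in range(spec.n_slices):
            r_k = r_eq * profile[k]
            for role, base_r in ((ENDO, r_k), (EPI, r_k + spec.wall_thickness_mm)):
                radii = base_r + rng.normal(0.0, 1.0, nv) * spec.noise_sd_mm
                pts = np.column_stack([radii * ca, radii * sa]) + offsets[k]
                contours.append(
                    Contour(points=pts, role=role, slice_index=k, phase_index=phase)
                )

    study = CineStudy(
        subject_id=f"phantom-{spec.seed}",
        contours=contours,
        slices=slices,
        timing=CineTiming(n_phases=spec.n_phases, cycle_duration_ms=spec.cycle_duration_ms),
        reference_angle_rad=spec.reference_angle_rad,
    )

    included = [s for s in slices if s.included]
    inc_mask = np.array([s.included for s in slices])
    r_eq_all = np.array([_equatorial_radius(v, L) for v in volumes])
    # midpoint-rule analytic slice sum over included slices, ml
    slice_areas = np.pi * (np.outer(r_eq_all, profile) ** 2)  # (phase, slice), mm^2
    slice_vols = slice_areas * th / 1000.0
    truth_curve = slice_vols[:, inc_mask].sum(axis=1)

    assignment = aha.assign_layers(included)
    seg_truth = np.zeros((N_SEGMENTS, spec.n_phases))
    for s in included:
        layer = assignment.layers[s.slice_index]
        segs = aha.SEGMENT_NUMBERS[layer]
        share = slice_vols[:, s.slice_index] / len(segs)
        for seg in segs:
            seg_truth[seg - 1] += share

    edv = float(truth_curve.max())
    esv = float(truth_curve.min())
    i_min = int(np.argmin(truth_curve))
    truth = PhantomTruth(
        volume_curve_ml=truth_curve,
        segment_volumes_ml=seg_truth,
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=edv - esv,
        ef_pct=100.0 * (edv - esv) / edv,
        time_to_min_pct=100.0 * i_min / spec.n_phases,
    )
    return study, truth
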