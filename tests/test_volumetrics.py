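"""Slice-summation volumetry: geometry primitives, preprocessing, curves, indices."""

import numpy as np
import pytest
import shapely

from cinevol import io, volumetrics as vm
from cinevol.phantom import PhantomSpec, generate_phantom

from conftest import circle_polygon, star_polygon


def _mk_study(slice_polys, zs, thickness=8.0, n_phases=2, ref=0.0, flags=None):
    """Build a study repeating each slice polygon at every phase."""
    flags = flags or {}
    slices = [
        io.SliceGeometry(slice_index=i, z_mm=z, thickness_mm=thickness,
                         mitral_valve_visible=flags.get(i, False))
        for i, z in enumerate(zs)
    ]
    contours = [
        io.Contour(points=np.asarray(poly, dtype=float), role=io.ENDO,
                   slice_index=i, phase_index=p)
        for p in range(n_phases)
        for i, poly in enumerate(slice_polys)
    ]
    timing = io.CineTiming(n_phases=n_phases, cycle_duration_ms=1000.0)
    return io.CineStudy(subject_id="test", contours=contours, slices=slices,
                        timing=timing, reference_angle_rad=ref)


# --------------------------------------------------------------------------- primitives

def test_polygon_area_examples():
    assert vm.polygon_area([[0, 0], [1, 0], [1, 1], [0, 1]]) == 1.0
    assert vm.polygon_area([[0, 0], [1, 0], [0, 1]]) == 0.5
    # orientation independence
    assert vm.polygon_area([[0, 0], [0, 1], [1, 1], [1, 0]]) == 1.0
    with pytest.raises(io.GeometryError):
        vm.polygon_area([[0, 0], [1, 1]])


def test_polygon_area_random_decagon_vs_monte_carlo():
    rng = np.random.default_rng(5)
    poly = star_polygon(rng, n_min=10, n_max=10)
    n = 8_000_000
    lo, hi = poly.min(axis=0), poly.max(axis=0)
    pts = rng.uniform(lo, hi, (n, 2))
    inside = shapely.contains_xy(shapely.Polygon(poly), pts[:, 0], pts[:, 1])
    mc = inside.mean() * np.prod(hi - lo)
    assert vm.polygon_area(poly) == pytest.approx(mc, rel=1e-3)


def test_polygon_centroid_examples():
    np.testing.assert_allclose(vm.polygon_centroid([[0, 0], [1, 0], [1, 1], [0, 1]]), [0.5, 0.5])
    np.testing.assert_allclose(vm.polygon_centroid([[0, 0], [3, 0], [0, 3]]), [1.0, 1.0])
    poly = star_polygon(np.random.default_rng(3))
    d = np.array([2.5, -1.25])
    np.testing.assert_allclose(vm.polygon_centroid(poly + d), vm.polygon_centroid(poly) + d,
                               atol=1e-12)
    with pytest.raises(io.GeometryError):
        vm.polygon_centroid([[0, 0], [1, 1], [2, 2]])


# --------------------------------------------------------------------------- exclusion

def test_exclude_slices():
    polys = [circle_polygon(20.0, 32)] * 12
    study = _mk_study(polys, np.linspace(90, 20, 12), flags={0: True, 1: True})
    out = vm.exclude_slices(study)
    assert len(out.slices) == 10
    assert all(s.included for s in out.slices)
    assert all(c.slice_index >= 2 for c in out.contours)

    none_flagged = _mk_study(polys[:5], np.linspace(90, 50, 5))
    assert len(vm.exclude_slices(none_flagged).slices) == 5

    small = _mk_study(polys[:4], np.linspace(90, 60, 4), flags={0: True, 1: True})
    with pytest.raises(io.SchemaError, match=">= 3"):
        vm.exclude_slices(small)


# --------------------------------------------------------------------------- alignment

def test_align_collinear_study_is_identity():
    polys = [circle_polygon(20.0, 64, centre=(0.5 * z, -0.2 * z)) for z in (80, 60, 40, 20)]
    study = _mk_study(polys, [80, 60, 40, 20])
    aligned = vm.align_slices(study)
    for c0, c1 in zip(sorted(study.contours, key=lambda c: (c.slice_index, c.phase_index)),
                      sorted(aligned.contours, key=lambda c: (c.slice_index, c.phase_index))):
        np.testing.assert_allclose(c1.points, c0.points, atol=1e-9)


def test_align_single_offset_slice_matches_closed_form_fit():
    zs = np.linspace(90, 9, 10)
    polys = [circle_polygon(20.0, 64) for _ in zs]
    polys[4] = circle_polygon(20.0, 64, centre=(5.0, 0.0))
    study = _mk_study(polys, zs)
    aligned = vm.align_slices(study)
    # independent least-squares oracle on the 10 centroid x-values
    cx = np.zeros(10)
    cx[4] = 5.0
    fit = np.polyval(np.polyfit(zs, cx, 1), zs)
    got = np.array([vm.polygon_centroid(aligned.get_contour(i, 0).points)[0] for i in range(10)])
    np.testing.assert_allclose(got, fit, atol=1e-9)


def test_alignment_preserves_global_volume_and_flattens_centroids():
    spec = PhantomSpec(misalignment_sd_mm=3.0, n_vertices=64, n_phases=4)
    study, _ = generate_phantom(spec)
    excluded = vm.exclude_slices(study)
    aligned = vm.align_slices(excluded)
    v_pre = vm.segment_volume_curve(excluded).global_volumes
    v_post = vm.segment_volume_curve(aligned).global_volumes
    np.testing.assert_allclose(v_post, v_pre, rtol=1e-12)
    # residuals of aligned centroids to a straight long-axis fit
    zmap = {s.slice_index: s.z_mm for s in aligned.slices}
    for phase in range(spec.n_phases):
        idx = [s.slice_index for s in aligned.slices]
        z = np.array([zmap[i] for i in idx])
        cent = np.array([vm.polygon_centroid(aligned.get_contour(i, phase).points) for i in idx])
        for dim in range(2):
            resid = cent[:, dim] - np.polyval(np.polyfit(z, cent[:, dim], 1), z)
            assert np.sqrt(np.mean(resid**2)) < 1e-6


# --------------------------------------------------------------------------- volume curves

def test_three_identical_circular_slices_closed_form():
    polys = [circle_polygon(10.0, 400)] * 3
    study = _mk_study(polys, [24.0, 16.0, 8.0], thickness=8.0)
    curve = vm.segment_volume_curve(study)
    expected = 3 * np.pi * 100.0 * 8.0 / 1000.0  # 7.5398 ml
    assert curve.global_volumes[0] == pytest.approx(expected, rel=1e-4)
    curve.check_conservation()


def test_rotational_phantom_segment_symmetry(analyzed_default):
    curve, _, truth = analyzed_default
    # per-layer volume split: 1/6 per basal/mid segment, 1/4 per apical segment
    np.testing.assert_allclose(curve.segment_volumes, truth.segment_volumes_ml, rtol=1e-3)
    # within-layer equality is exact up to polygon chord effects (60-degree
    # wedge boundaries fall at different offsets within the 400-gon edges)
    for segs in ((0, 6), (6, 12)):
        block = curve.segment_volumes[segs[0]:segs[1]]
        np.testing.assert_allclose(block, np.broadcast_to(block.mean(axis=0), block.shape),
                                   rtol=1e-5)
    apical = curve.segment_volumes[12:16]  # 4 divides 400: exact symmetry
    np.testing.assert_allclose(apical, np.broadcast_to(apical.mean(axis=0), apical.shape),
                               rtol=1e-12)


def test_global_volume_invariant_to_reference_angle_and_translation():
    spec = PhantomSpec(n_vertices=64, n_phases=3, noise_sd_mm=0.3)
    study, _ = generate_phantom(spec)
    study = vm.exclude_slices(study)
    base = vm.segment_volume_curve(study)
    study_rot = io.CineStudy(subject_id=study.subject_id, contours=study.contours,
                             slices=study.slices, timing=study.timing,
                             reference_angle_rad=1.234)
    rot = vm.segment_volume_curve(study_rot)
    np.testing.assert_allclose(rot.global_volumes, base.global_volumes, rtol=1e-12)
    # whole-slice translation
    moved = [io.Contour(points=c.points + np.array([7.0, -3.0]), role=c.role,
                        slice_index=c.slice_index, phase_index=c.phase_index)
             for c in study.contours]
    study_mv = io.CineStudy(subject_id=study.subject_id, contours=moved,
                            slices=study.slices, timing=study.timing,
                            reference_angle_rad=study.reference_angle_rad)
    mv = vm.segment_volume_curve(study_mv)
    np.testing.assert_allclose(mv.global_volumes, base.global_volumes, rtol=1e-12)


def test_isotropic_scaling_scales_volumes_quadratically():
    spec = PhantomSpec(n_vertices=64, n_phases=3)
    study, _ = generate_phantom(spec)
    study = vm.exclude_slices(study)
    base = vm.segment_volume_curve(study)
    s = 1.3
    scaled_contours = [io.Contour(points=c.points * s, role=c.role,
                                  slice_index=c.slice_index, phase_index=c.phase_index)
                       for c in study.contours]
    scaled = io.CineStudy(subject_id=study.subject_id, contours=scaled_contours,
                          slices=study.slices, timing=study.timing)
    sc = vm.segment_volume_curve(scaled)
    np.testing.assert_allclose(sc.global_volumes, s**2 * base.global_volumes, rtol=1e-12)
    ef_base = vm.function_indices(base, study.timing).ef_pct
    ef_scaled = vm.function_indices(sc, study.timing).ef_pct
    assert ef_scaled == pytest.approx(ef_base, abs=1e-9)


def test_global_volume_matches_voxelization_oracle():
    """Brute-force 0.5 mm point-in-polygon grid agrees with the slice sum."""
    spec = PhantomSpec(n_vertices=100, n_phases=2, noise_sd_mm=0.5, seed=23)
    study, _ = generate_phantom(spec)
    study = vm.exclude_slices(study)
    curve = vm.segment_volume_curve(study)
    h = 0.5
    for phase in range(2):
        vol = 0.0
        for s in study.slices:
            pts = study.get_contour(s.slice_index, phase).points
            lo = np.floor(pts.min(axis=0)) - 1
            hi = np.ceil(pts.max(axis=0)) + 1
            gx, gy = np.meshgrid(np.arange(lo[0], hi[0], h) + h / 2,
                                 np.arange(lo[1], hi[1], h) + h / 2)
            inside = shapely.contains_xy(shapely.Polygon(pts), gx.ravel(), gy.ravel())
            vol += inside.sum() * h * h * s.thickness_mm / 1000.0
        assert vol == pytest.approx(curve.global_volumes[phase], rel=5e-3)


def test_z_spacing_mode_equals_thickness_for_contiguous_stack():
    spec = PhantomSpec(n_vertices=64, n_phases=2)
    study, _ = generate_phantom(spec)
    study = vm.exclude_slices(study)
    a = vm.segment_volume_curve(study, spacing_mode="thickness")
    b = vm.segment_volume_curve(study, spacing_mode="z_spacing")
    # interior weights coincide for a contiguous stack; only the stack ends differ
    np.testing.assert_allclose(b.global_volumes, a.global_volumes, rtol=0.2)
    with pytest.raises(ValueError):
        vm.segment_volume_curve(study, spacing_mode="bogus")


# --------------------------------------------------------------------------- indices

def _curve_from_global(g):
    g = np.asarray(g, dtype=float)
    seg = np.tile(g / 16.0, (16, 1))
    return io.VolumeCurve(segment_volumes=seg, global_volumes=g)


def test_function_indices_examples():
    timing = io.CineTiming(n_phases=5, cycle_duration_ms=1000.0)
    idx = vm.function_indices(_curve_from_global([100, 80, 50, 70, 95]), timing)
    assert (idx.edv_ml, idx.esv_ml, idx.sv_ml) == (100.0, 50.0, 50.0)
    assert idx.ef_pct == pytest.approx(50.0)
    assert idx.time_to_min_pct == pytest.approx(40.0)


def test_function_indices_reference_mean_volumes():
    """Mean EDV/ESV of a reference CMR analysis imply SV = EDV - ESV."""
    timing = io.CineTiming(n_phases=2, cycle_duration_ms=1000.0)
    idx = vm.function_indices(_curve_from_global([167.05, 95.54]), timing)
    assert idx.sv_ml == pytest.approx(71.51, abs=1e-9)


def test_constant_curve_gives_zero_sv_and_ef():
    timing = io.CineTiming(n_phases=3, cycle_duration_ms=900.0)
    idx = vm.function_indices(_curve_from_global([90, 90, 90]), timing)
    assert idx.sv_ml == 0.0
    assert idx.ef_pct == 0.0
    assert idx.time_to_min_pct == 0.0  # tie-break to the earliest phase


def test_time_to_max_contraction():
    timing = io.CineTiming(n_phases=20, cycle_duration_ms=1000.0)
    g = np.full(20, 100.0)
    g[8] = 40.0
    assert vm.time_to_max_contraction(_curve_from_global(g), timing) == pytest.approx(40.0)
    g2 = np.linspace(50, 100, 20)
    assert vm.time_to_max_contraction(_curve_from_global(g2), timing) == 0.0


@pytest.mark.parametrize("ef", [15.0, 20.0, 35.0, 60.0])
@pytest.mark.parametrize("edv", [120.0, 200.0, 280.0])
def test_phantom_ef_recovery_grid(ef, edv):
    spec = PhantomSpec(ef_pct=ef, edv_ml=edv, n_slices=10, slice_thickness_mm=8.0,
                       n_vertices=100, n_phases=10)
    study, _ = generate_phantom(spec)
    _, idx = vm.analyze_study(study)
    assert idx.ef_pct == pytest.approx(ef, abs=2.0)
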