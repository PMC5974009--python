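"""Contour-stack data model and serialization.

The core container is :class:`CineStudy`: a stack of short-axis slices of the
left ventricle, each carrying closed endocardial (and optionally epicardial)
contours for every phase of one averaged cardiac cycle, together with slice
geometry (z-position along the long axis, slice thickness) and cycle timing.
Coordinates are physical millimetres in-plane; pixel-to-mm conversion is
assumed to have happened upstream, in the segmentation step that produced the
contours.  z decreases from base to apex, and base/apex ordering is always
derived from z, never from slice numbering.

Studies round-trip through a JSON schema; volume-time curves and function
indices are written as CSV plus a JSON sidecar.  Serialization is
deterministic (sorted keys, shortest round-trip float repr) so that identical
studies produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "ENDO",
    "EPI",
    "N_SEGMENTS",
    "SchemaError",
    "GeometryError",
    "Contour",
    "SliceGeometry",
    "CineTiming",
    "CineStudy",
    "VolumeCurve",
    "FunctionIndices",
    "load_study",
    "save_study",
    "write_curves",
    "read_curves",
    "read_indices",
    "studies_equal",
]

ENDO = "endo"
EPI = "epi"
N_SEGMENTS = 16


class SchemaError(ValueError):
    """Study file or in-memory study violates the schema/invariants."""


class GeometryError(ValueError):
    """A contour is geometrically invalid (degenerate or self-intersecting)."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise SchemaError(f"contour points must be an (n, 2) array, got shape {pts.shape}")
    return pts


@dataclass(eq=False)
class Contour:
    """One closed planar polygon (endo- or epicardium) on one slice and phase.

    The polygon is stored as an ordered vertex list with the closing edge
    implicit.  Orientation is unconstrained; all area computations use the
    absolute shoelace value.
    """

    points: np.ndarray
    role: str
    slice_index: int
    phase_index: int

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if self.role not in (ENDO, EPI):
            raise SchemaError(f"contour role must be {ENDO!r} or {EPI!r}, got {self.role!r}")
        if len(self.points) < 3:
            raise GeometryError(
                f"contour (slice {self.slice_index}, phase {self.phase_index}, "
                f"role {self.role}) has {len(self.points)} points; need >= 3"
            )
        if not np.all(np.isfinite(self.points)):
            raise GeometryError(
                f"contour (slice {self.slice_index}, phase {self.phase_index}, "
                f"role {self.role}) has non-finite coordinates"
            )

    def validate_simple(self) -> None:
        """Raise GeometryError unless the polygon is simple with positive area."""
        poly = _ShapelyPolygon(self.points)
        if not poly.is_valid or poly.area <= 0.0:
            raise GeometryError(
                f"contour (slice {self.slice_index}, phase {self.phase_index}, "
                f"role {self.role}) is not a simple polygon with positive area"
            )


@dataclass(frozen=True)
class SliceGeometry:
    """Geometry and inclusion flags of one short-axis slice.

    ``z_mm`` is the slice midplane position along the LV long axis, decreasing
    toward the apex.  ``mitral_valve_visible`` marks basal slices in which the
    mitral valve appears; ``beyond_lv`` marks slices outside the ventricle.
    Both are excluded from all volume computations.
    """

    slice_index: int
    z_mm: float
    thickness_mm: float
    mitral_valve_visible: bool = False
    beyond_lv: bool = False

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise SchemaError(f"slice {self.slice_index}: thickness must be > 0, got {self.thickness_mm}")

    @property
    def included(self) -> bool:
        return not (self.mitral_valve_visible or self.beyond_lv)


@dataclass(frozen=True)
class CineTiming:
    """Cardiac-cycle timing of the cine acquisition.

    If ``phase_times_ms`` is omitted, phase i occurs at i * cycle / n_phases
    (uniform retrospective gating).
    """

    n_phases: int
    cycle_duration_ms: float
    phase_times_ms: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise SchemaError(f"n_phases must be >= 2, got {self.n_phases}")
        if self.cycle_duration_ms <= 0:
            raise SchemaError(f"cycle_duration_ms must be > 0, got {self.cycle_duration_ms}")
        if self.phase_times_ms is not None:
            t = tuple(float(v) for v in self.phase_times_ms)
            object.__setattr__(self, "phase_times_ms", t)
            if len(t) != self.n_phases:
                raise SchemaError(
                    f"phase_times_ms has length {len(t)}, expected n_phases={self.n_phases}"
                )
            if any(b <= a for a, b in zip(t, t[1:])):
                raise SchemaError("phase_times_ms must be strictly increasing")
            if t[-1] >= self.cycle_duration_ms:
                raise SchemaError("phase_times_ms must all be < cycle_duration_ms")

    def phase_time(self, phase_index: int) -> float:
        """Time of a phase in ms from the cycle trigger."""
        if not 0 <= phase_index < self.n_phases:
            raise IndexError(f"phase_index {phase_index} out of range [0, {self.n_phases})")
        if self.phase_times_ms is not None:
            return self.phase_times_ms[phase_index]
        return phase_index * self.cycle_duration_ms / self.n_phases


@dataclass(eq=False)
class CineStudy:
    """A full contour stack: slices x phases x contours plus timing.

    ``reference_angle_rad`` is the direction (radians, in-plane) of the
    anterior RV-insertion reference used to orient the AHA sectors; the
    upstream system derives it from long-axis views, so here it is an input.
    """

    subject_id: str
    contours: list[Contour]
    slices: list[SliceGeometry]
    timing: CineTiming
    reference_angle_rad: float = 0.0

    def slice_map(self) -> dict[int, SliceGeometry]:
        return {s.slice_index: s for s in self.slices}

    def included_slices(self) -> list[SliceGeometry]:
        """Included slices sorted base -> apex (decreasing z)."""
        return sorted((s for s in self.slices if s.included), key=lambda s: -s.z_mm)

    def contour_map(self) -> dict[tuple[int, int, str], Contour]:
        out: dict[tuple[int, int, str], Contour] = {}
        for c in self.contours:
            key = (c.slice_index, c.phase_index, c.role)
            if key in out:
                raise SchemaError(
                    f"duplicate contour for slice {key[0]}, phase {key[1]}, role {key[2]}"
                )
            out[key] = c
        return out

    def get_contour(self, slice_index: int, phase_index: int, role: str = ENDO) -> Contour:
        for c in self.contours:
            if (c.slice_index, c.phase_index, c.role) == (slice_index, phase_index, role):
                return c
        raise SchemaError(f"missing contour for slice {slice_index}, phase {phase_index}, role {role}")


def validate_study(study: CineStudy, check_geometry: bool = True) -> None:
    """Check all CineStudy invariants; raise SchemaError/GeometryError naming the offender."""
    seen = set()
    for s in study.slices:
        if s.slice_index in seen:
            raise SchemaError(f"duplicate slice_index {s.slice_index}")
        seen.add(s.slice_index)
    cmap = study.contour_map()  # raises on duplicates
    for c in study.contours:
        if c.slice_index not in seen:
            raise SchemaError(
                f"contour references unknown slice_index {c.slice_index} "
                f"(phase {c.phase_index}, role {c.role})"
            )
        if not 0 <= c.phase_index < study.timing.n_phases:
            raise SchemaError(
                f"contour phase_index {c.phase_index} out of range for "
                f"n_phases={study.timing.n_phases} (slice {c.slice_index}, role {c.role})"
            )
    for s in study.slices:
        if not s.included:
            continue
        for p in range(study.timing.n_phases):
            if (s.slice_index, p, ENDO) not in cmap:
                raise SchemaError(
                    f"missing contour for slice {s.slice_index}, phase {p}, role {ENDO}"
                )
    if check_geometry:
        for c in study.contours:
            c.validate_simple()


@dataclass(eq=False)
class VolumeCurve:
    """Per-segment (16 x n_phases) and global (n_phases) volumes in ml.

    The global volume is computed independently from the full endocardial
    polygon areas; agreement with the segment sum is a conservation check,
    not a tautology.
    """

    segment_volumes: np.ndarray
    global_volumes: np.ndarray

    def __post_init__(self) -> None:
        self.segment_volumes = np.asarray(self.segment_volumes, dtype=float)
        self.global_volumes = np.asarray(self.global_volumes, dtype=float)
        if self.segment_volumes.ndim != 2 or self.segment_volumes.shape[0] != N_SEGMENTS:
            raise SchemaError(
                f"segment_volumes must be ({N_SEGMENTS}, n_phases), got {self.segment_volumes.shape}"
            )
        if self.global_volumes.shape != (self.segment_volumes.shape[1],):
            raise SchemaError("global_volumes length must match segment_volumes phases")
        if np.any(self.segment_volumes < 0) or np.any(self.global_volumes < 0):
            raise SchemaError("volumes must be non-negative")

    @property
    def n_phases(self) -> int:
        return self.segment_volumes.shape[1]

    def check_conservation(self, rtol: float = 1e-9) -> None:
        seg_sum = self.segment_volumes.sum(axis=0)
        scale = np.maximum(np.abs(self.global_volumes), 1e-30)
        err = np.max(np.abs(seg_sum - self.global_volumes) / scale)
        if err > rtol:
            raise SchemaError(
                f"segment volumes do not sum to the global volume (max rel err {err:.3e})"
            )


@dataclass(frozen=True)
class FunctionIndices:
    """Global LV function indices derived from a volume-time curve.

    EDV and ESV are the curve maximum and minimum (end-diastolic and
    end-systolic volumes), SV = EDV - ESV, EF = SV/EDV * 100%, and
    ``time_to_min_pct`` is the time of minimal volume (maximal contraction)
    as a percentage of the cardiac cycle.
    """

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    time_to_min_pct: float

    def __post_init__(self) -> None:
        if self.esv_ml > self.edv_ml + 1e-12:
            raise SchemaError("ESV must not exceed EDV")
        if abs(self.sv_ml - (self.edv_ml - self.esv_ml)) > 1e-9 * max(1.0, self.edv_ml):
            raise SchemaError("SV must equal EDV - ESV")
        if not 0.0 <= self.ef_pct <= 100.0:
            raise SchemaError(f"EF must be in [0, 100], got {self.ef_pct}")
        if not 0.0 <= self.time_to_min_pct < 100.0:
            raise SchemaError(f"time_to_min_pct must be in [0, 100), got {self.time_to_min_pct}")


# ---------------------------------------------------------------------------
# JSON study serialization


def _study_to_obj(study: CineStudy) -> dict:
    return {
        "subject_id": study.subject_id,
        "reference_angle_rad": float(study.reference_angle_rad),
        "timing": {
            "n_phases": study.timing.n_phases,
            "cycle_duration_ms": float(study.timing.cycle_duration_ms),
            **(
                {"phase_times_ms": list(study.timing.phase_times_ms)}
                if study.timing.phase_times_ms is not None
                else {}
            ),
        },
        "slices": [
            {
                "slice_index": s.slice_index,
                "z_mm": float(s.z_mm),
                "thickness_mm": float(s.thickness_mm),
                "mitral_valve_visible": bool(s.mitral_valve_visible),
                "beyond_lv": bool(s.beyond_lv),
            }
            for s in sorted(study.slices, key=lambda s: s.slice_index)
        ],
        "contours": [
            {
                "slice_index": c.slice_index,
                "phase_index": c.phase_index,
                "role": c.role,
                "points": [[float(x), float(y)] for x, y in c.points],
            }
            for c in sorted(study.contours, key=lambda c: (c.slice_index, c.phase_index, c.role))
        ],
    }


def save_study(study: CineStudy, path: str | Path) -> None:
    """Write a validated study to JSON.

    Output is deterministic: two saves of the same study are byte-identical.
    """
    validate_study(study)
    text = json.dumps(_study_to_obj(study), sort_keys=True, indent=None, separators=(",", ":"))
    Path(path).write_text(text + "\n")


def load_study(path: str | Path) -> CineStudy:
    """Read and validate a study JSON file."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except FileNotFoundError:
        raise
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    for key in ("subject_id", "timing", "slices", "contours"):
        if key not in obj:
            raise SchemaError(f"{path}: missing required block {key!r}")
    t = obj["timing"]
    for key in ("n_phases", "cycle_duration_ms"):
        if key not in t:
            raise SchemaError(f"{path}: timing block missing {key!r}")
    timing = CineTiming(
        n_phases=int(t["n_phases"]),
        cycle_duration_ms=float(t["cycle_duration_ms"]),
        phase_times_ms=tuple(t["phase_times_ms"]) if t.get("phase_times_ms") is not None else None,
    )
    slices = [
        SliceGeometry(
            slice_index=int(s["slice_index"]),
            z_mm=float(s["z_mm"]),
            thickness_mm=float(s["thickness_mm"]),
            mitral_valve_visible=bool(s.get("mitral_valve_visible", False)),
            beyond_lv=bool(s.get("beyond_lv", False)),
        )
        for s in obj["slices"]
    ]
    contours = [
        Contour(
            points=np.asarray(c["points"], dtype=float),
            role=str(c["role"]),
            slice_index=int(c["slice_index"]),
            phase_index=int(c["phase_index"]),
        )
        for c in obj["contours"]
    ]
    study = CineStudy(
        subject_id=str(obj["subject_id"]),
        contours=contours,
        slices=slices,
        timing=timing,
        reference_angle_rad=float(obj.get("reference_angle_rad", 0.0)),
    )
    validate_study(study)
    return study


def studies_equal(a: CineStudy, b: CineStudy, tol: float = 0.0) -> bool:
    """Field-by-field equality of two studies (coordinates within ``tol`` mm)."""
    if a.subject_id != b.subject_id:
        return False
    if abs(a.reference_angle_rad - b.reference_angle_rad) > tol:
        return False
    if a.timing != b.timing:
        return False
    if sorted(a.slices, key=lambda s: s.slice_index) != sorted(b.slices, key=lambda s: s.slice_index):
        return False
    ka = sorted(a.contours, key=lambda c: (c.slice_index, c.phase_index, c.role))
    kb = sorted(b.contours, key=lambda c: (c.slice_index, c.phase_index, c.role))
    if len(ka) != len(kb):
        return False
    for ca, cb in zip(ka, kb):
        if (ca.slice_index, ca.phase_index, ca.role) != (cb.slice_index, cb.phase_index, cb.role):
            return False
        if ca.points.shape != cb.points.shape:
            return False
        if not np.allclose(ca.points, cb.points, rtol=0.0, atol=tol):
            return False
    return True


# ---------------------------------------------------------------------------
# Curve / indices output


def write_curves(
    curve: VolumeCurve,
    indices: FunctionIndices,
    path: str | Path,
    timing: CineTiming,
    indices_path: str | Path | None = None,
) -> None:
    """Write a volume-time curve as CSV and the function indices as JSON.

    CSV columns: phase, time_ms, global_ml, seg01..seg16 — one row per phase.
    The indices sidecar defaults to ``<path>`` with an ``.indices.json`` suffix.
    """
    if timing.n_phases != curve.n_phases:
        raise SchemaError(
            f"timing has {timing.n_phases} phases but curve has {curve.n_phases}"
        )
    curve.check_conservation()
    # consistency: the indices must describe this curve
    if abs(indices.edv_ml - float(curve.global_volumes.max())) > 1e-6 or abs(
        indices.esv_ml - float(curve.global_volumes.min())
    ) > 1e-6:
        raise SchemaError("function indices are not derived from this curve")
    cols = {
        "phase": np.arange(curve.n_phases, dtype=int),
        "time_ms": [timing.phase_time(i) for i in range(curve.n_phases)],
        "global_ml": curve.global_volumes,
    }
    for k in range(N_SEGMENTS):
        cols[f"seg{k + 1:02d}"] = curve.segment_volumes[k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    if indices_path is None:
        indices_path = Path(path).with_suffix(".indices.json")
    obj = {
        "edv_ml": indices.edv_ml,
        "esv_ml": indices.esv_ml,
        "sv_ml": indices.sv_ml,
        "ef_pct": indices.ef_pct,
        "time_to_min_pct": indices.time_to_min_pct,
    }
    Path(indices_path).write_text(json.dumps(obj, sort_keys=True) + "\n")


def read_curves(path: str | Path) -> pd.DataFrame:
    """Read a curve CSV written by :func:`write_curves`."""
    df = pd.read_csv(path)
    expected = ["phase", "time_ms", "global_ml"] + [f"seg{k + 1:02d}" for k in range(N_SEGMENTS)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: curve CSV missing columns {missing}")
    return df


def read_indices(path: str | Path) -> FunctionIndices:
    obj = json.loads(Path(path).read_text())
    return FunctionIndices(
        edv_ml=float(obj["edv_ml"]),
        esv_ml=float(obj["esv_ml"]),
        sv_ml=float(obj["sv_ml"]),
        ef_pct=float(obj["ef_pct"]),
        time_to_min_pct=float(obj["time_to_min_pct"]),
    )
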