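"""AHA 16-segment division of the LV short-axis stack.

Slices are grouped into three contiguous long-axis layers (basal, mid,
apical); each endocardial contour is then split into angular sectors about
its centroid — six sectors of 60 degrees for basal and mid layers, four of
90 degrees for the apical layer — giving 6 + 6 + 4 = 16 segments.  The
apical cap (segment 17 of the full AHA model) is not part of the short-axis
blood-pool stack and is excluded.

Sector boundaries are measured counterclockwise from a per-study reference
direction (the anterior RV-insertion point, supplied as an input), with the
anterior segment first, so numbering is 1-6 basal, 7-12 mid, 13-16 apical.

Sector areas are computed by exact polygon clipping: each sector wedge is
convex (opening angle <= pi), so two successive half-plane clips
(Sutherland-Hodgman) of the contour against the wedge boundary rays suffice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Contour, GeometryError, SliceGeometry

__all__ = [
    "BASAL",
    "MID",
    "APICAL",
    "LAYERS",
    "SEGMENT_NUMBERS",
    "LayerAssignment",
    "SectorSpec",
    "assign_layers",
    "sector_spec",
    "clip_to_sector",
    "segment_areas",
    "point_in_polygon",
]

BASAL = "basal"
MID = "mid"
APICAL = "apical"
LAYERS = (BASAL, MID, APICAL)

# AHA segment numbers per layer, anterior first, counterclockwise.
SEGMENT_NUMBERS = {
    BASAL: (1, 2, 3, 4, 5, 6),
    MID: (7, 8, 9, 10, 11, 12),
    APICAL: (13, 14, 15, 16),
}


@dataclass(frozen=True)
class LayerAssignment:
    """Layer label per included slice, contiguous in z (base -> apex)."""

    layers: dict[int, str]  # slice_index -> layer
    order: tuple[int, ...]  # slice indices sorted base -> apex

    def slices_in(self, layer: str) -> tuple[int, ...]:
        return tuple(i for i in self.order if self.layers[i] == layer)


@dataclass(frozen=True)
class SectorSpec:
    """Angular intervals (half-open, counterclockwise) of one layer's sectors."""

    layer: str
    intervals: tuple[tuple[float, float, int], ...]  # (theta0, theta1, segment number)


def assign_layers(slices: list[SliceGeometry]) -> LayerAssignment:
    """Split included slices into basal/mid/apical thirds by slice count.

    Slices are ordered base -> apex by decreasing z.  For n = 3q + r the
    remainder slices go one each to the basal, then the mid layer, keeping
    the three groups contiguous.
    """
    ordered = sorted(slices, key=lambda s: -s.z_mm)
    n = len(ordered)
    if n < 3:
        raise ValueError(f"need >= 3 included slices to form three layers, got {n}")
    q, r = divmod(n, 3)
    counts = (q + (1 if r >= 1 else 0), q + (1 if r >= 2 else 0), q)
    layers: dict[int, str] = {}
    pos = 0
    for layer, cnt in zip(LAYERS, counts):
        for s in ordered[pos : pos + cnt]:
            layers[s.slice_index] = layer
        pos += cnt
    return LayerAssignment(layers=layers, order=tuple(s.slice_index for s in ordered))


def sector_spec(layer: str, reference_angle: float) -> SectorSpec:
    """Sector boundaries of a layer, counterclockwise from the reference direction."""
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    segs = SEGMENT_NUMBERS[layer]
    width = 2.0 * np.pi / len(segs)
    intervals = tuple(
        (reference_angle + i * width, reference_angle + (i + 1) * width, seg)
        for i, seg in enumerate(segs)
    )
    return SectorSpec(layer=layer, intervals=intervals)


def point_in_polygon(points: np.ndarray, p) -> bool:
    """Even-odd ray-cast point-in-polygon test (boundary points unspecified)."""
    x, y = float(p[0]), float(p[1])
    x0, y0 = points[:, 0], points[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    crosses = (y0 > y) != (y1 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
    return bool(np.count_nonzero(crosses & (x < xi)) % 2)


def _clip_halfplane(pts: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clip of a closed polygon against dot(p-origin, n) >= 0."""
    if len(pts) == 0:
        return pts
    d = (pts - origin) @ normal
    keep = d >= 0.0
    if keep.all():
        return pts
    if not keep.any():
        return pts[:0]
    dn = np.roll(d, -1)
    keepn = np.roll(keep, -1)
    cross = keep != keepn
    pn = np.roll(pts, -1, axis=0)
    out_counts = keep.astype(np.intp) + cross.astype(np.intp)
    idx = np.cumsum(out_counts)
    start = idx - out_counts
    out = np.empty((int(idx[-1]), 2), dtype=float)
    out[start[keep]] = pts[keep]
    if cross.any():
        t = d[cross] / (d[cross] - dn[cross])
        inter = pts[cross] + t[:, None] * (pn[cross] - pts[cross])
        out[(start + keep.astype(np.intp))[cross]] = inter
    return out


def _contour_points(contour) -> np.ndarray:
    if isinstance(contour, Contour):
        return contour.points
    return np.asarray(contour, dtype=float)


def clip_to_sector(contour, centre, theta0: float, theta1: float) -> np.ndarray:
    """Intersect a contour with the convex wedge between two rays from ``centre``.

    The wedge spans counterclockwise from ``theta0`` to ``theta1`` with
    0 < theta1 - theta0 <= pi.  Returns the clipped polygon vertices (possibly
    empty).  The centre must lie strictly inside the contour.
    """
    span = theta1 - theta0
    if not 0.0 < span <= np.pi + 1e-12:
        raise ValueError(f"wedge span must be in (0, pi], got {span}")
    pts = _contour_points(contour)
    c = np.asarray(centre, dtype=float)
    if not point_in_polygon(pts, c):
        raise GeometryError("sector centre lies outside the contour")
    return _clip_wedge(pts, c, theta0, theta1)


def _clip_wedge(pts: np.ndarray, c: np.ndarray, theta0: float, theta1: float) -> np.ndarray:
    # left of the theta0 ray and right of the theta1 ray
    n0 = np.array([-np.sin(theta0), np.cos(theta0)])
    n1 = np.array([np.sin(theta1), -np.cos(theta1)])
    return _clip_halfplane(_clip_halfplane(pts, c, n0), c, n1)


def _shoelace(pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def segment_areas(contour, centre, spec: SectorSpec) -> dict[int, float]:
    """Area (mm^2) of each AHA sector of one contour about ``centre``.

    The wedges partition the plane, so the returned areas sum to the full
    contour area up to floating-point rounding.
    """
    pts = _contour_points(contour)
    c = np.asarray(centre, dtype=float)
    if not point_in_polygon(pts, c):
        raise GeometryError("sector centre lies outside the contour")
    return {
        seg: _shoelace(_clip_wedge(pts, c, t0, t1)) for t0, t1, seg in spec.intervals
    }
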