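"""EM dyad morphometry from traced contour scenes.

Three metrics characterise a dyad cross-section traced from a transmission
electron micrograph:

* circularity of the T-tubule contour, 4*pi*A / P^2 (1 for a circle);
* coupling ratio, the fraction of the T-tubule perimeter lying within
  d_max of a junctional-SR trace (default d_max 15 nm, slightly above the
  ~12 nm dyadic cleft to tolerate tracing error);
* junction-Z-line distance, the perpendicular distance from the Z-line to
  the arc-length midpoint of the largest coupled perimeter run.

All coordinates are in nanometres.  Scenes are stored as JSON:
{"unit":"nm","ttubule":[[x,y],...],"jsr":[[[x,y],...],...],
 "zline":{"point":[x,y],"direction":[dx,dy]},"truth":{...}}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

DEFAULT_D_MAX_NM = 15.0
RESAMPLE_STEP_NM = 1.0


@dataclass
class EMScene:
    ttubule: np.ndarray                 # (n, 2) closed polygon, nm
    jsr: list[np.ndarray] = field(default_factory=list)  # polylines, nm
    zline: tuple[np.ndarray, np.ndarray] | None = None   # (point, direction)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.ttubule = np.asarray(self.ttubule, dtype=float)
        if self.ttubule.ndim != 2 or self.ttubule.shape[1] != 2 or len(self.ttubule) < 3:
            raise ValueError("ttubule must be an (n>=3, 2) polygon")
        self.jsr = [np.asarray(p, dtype=float) for p in self.jsr]
        if self.zline is not None:
            pt, d = (np.asarray(self.zline[0], dtype=float),
                     np.asarray(self.zline[1], dtype=float))
            if np.hypot(*d) == 0:
                raise ValueError("zline direction must be non-zero")
            self.zline = (pt, d)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "unit": "nm",
            "ttubule": self.ttubule.tolist(),
            "jsr": [p.tolist() for p in self.jsr],
            "zline": None if self.zline is None else {
                "point": self.zline[0].tolist(),
                "direction": self.zline[1].tolist(),
            },
            "truth": self.truth,
        }
        Path(path).write_text(json.dumps(obj) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EMScene":
        obj = json.loads(Path(path).read_text())
        z = obj.get("zline")
        return cls(
            ttubule=np.asarray(obj["ttubule"], dtype=float),
            jsr=[np.asarray(p, dtype=float) for p in obj.get("jsr", [])],
            zline=None if z is None else (np.asarray(z["point"]), np.asarray(z["direction"])),
            truth=obj.get("truth"),
        )


@dataclass
class DyadGeometryMetrics:
    circularity: float
    coupling_ratio: float
    junction_z_distance_nm: float | None  # None when no junction exists


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def circularity(polygon: np.ndarray) -> float:
    """Shape compactness 4*pi*A/P^2 of a simple closed polygon."""
    polygon = np.asarray(polygon, dtype=float)
    if len(polygon) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    sp = _ShapelyPolygon(polygon)
    if not sp.is_valid or not sp.is_simple:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    area = _shoelace_area(polygon)
    if area <= 0:
        raise ValueError("degenerate polygon (zero area)")
    per = _perimeter(polygon)
    return 4.0 * math.pi * area / (per * per)


def _resample_perimeter(poly: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Uniform arc-length resampling of a closed polygon.

    Returns (points, arc positions, total perimeter); spacing <= step.
    """
    closed = np.vstack([poly, poly[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    n = max(int(math.ceil(total / step)), 8)
    si = np.linspace(0.0, total, n, endpoint=False)
    xi = np.interp(si, s, closed[:, 0])
    yi = np.interp(si, s, closed[:, 1])
    return np.column_stack([xi, yi]), si, total


def _min_dist_to_polylines(points: np.ndarray, polylines: list[np.ndarray]) -> np.ndarray:
    """Minimum distance from each point to any segment of any polyline."""
    best = np.full(len(points), np.inf)
    for pl in polylines:
        if len(pl) == 0:
            continue
        if len(pl) == 1:
            d = np.hypot(points[:, 0] - pl[0, 0], points[:, 1] - pl[0, 1])
            best = np.minimum(best, d)
            continue
        a = pl[:-1]          # (m, 2)
        ab = pl[1:] - a      # (m, 2)
        ab2 = np.einsum("ij,ij->i", ab, ab)
        ab2[ab2 == 0] = 1.0
        # (n, m) projections, chunked over points to bound memory
        for lo in range(0, len(points), 2048):
            p = points[lo:lo + 2048]
            ap = p[:, None, :] - a[None, :, :]
            tpar = np.clip(np.einsum("nmj,mj->nm", ap, ab) / ab2[None, :], 0.0, 1.0)
            diff = ap - tpar[:, :, None] * ab[None, :, :]
            d = np.sqrt(np.einsum("nmj,nmj->nm", diff, diff)).min(axis=1)
            best[lo:lo + 2048] = np.minimum(best[lo:lo + 2048], d)
    return best


def _coupled_mask(ttubule: np.ndarray, jsr: list[np.ndarray], d_max_nm: float
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    pts, s, total = _resample_perimeter(np.asarray(ttubule, dtype=float), RESAMPLE_STEP_NM)
    jsr = [p for p in jsr if len(p) > 0]
    if not jsr:
        return np.zeros(len(pts), dtype=bool), s, total
    d = _min_dist_to_polylines(pts, jsr)
    return d <= d_max_nm, s, total


def coupling_ratio(ttubule: np.ndarray, jsr: list[np.ndarray],
                   d_max_nm: float = DEFAULT_D_MAX_NM) -> float:
    """Fraction of T-tubule perimeter within d_max of any jSR trace."""
    if d_max_nm <= 0:
        raise ValueError("d_max_nm must be positive")
    mask, _s, _total = _coupled_mask(ttubule, jsr, d_max_nm)
    return float(mask.mean())


def _largest_circular_run(mask: np.ndarray) -> tuple[int, int]:
    """Start index and length of the longest run of True, circularly."""
    n = len(mask)
    if mask.all():
        return 0, n
    # rotate so index 0 is False, then runs cannot wrap
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    best_len = best_start = 0
    run_start = None
    for i, v in enumerate(np.concatenate([rolled, [False]])):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    return (best_start + first_false) % n, best_len


def _polyline_arc_midpoint(pl: np.ndarray) -> np.ndarray:
    seg = np.diff(pl, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(lens)])
    half = s[-1] / 2.0
    x = np.interp(half, s, pl[:, 0])
    y = np.interp(half, s, pl[:, 1])
    return np.array([x, y])


def _point_line_distance(q: np.ndarray, point: np.ndarray, direction: np.ndarray) -> float:
    d = direction / np.hypot(*direction)
    v = q - point
    return float(abs(v[0] * d[1] - v[1] * d[0]))


def junction_z_distance(ttubule: np.ndarray, jsr: list[np.ndarray],
                        zline: tuple[np.ndarray, np.ndarray],
                        d_max_nm: float = DEFAULT_D_MAX_NM) -> float:
    """Perpendicular distance (nm) from the Z-line to the dyad junction.

    The junction is the arc-length midpoint of the largest coupled perimeter
    run.  With full jSR wrap there is no run boundary; the junction then
    falls back to the perimeter point nearest the jSR trace's own arc
    midpoint.
    """
    mask, s, total = _coupled_mask(ttubule, jsr, d_max_nm)
    if not mask.any():
        raise ValueError("no junction: no coupled perimeter run within d_max")
    pts, _, _ = _resample_perimeter(np.asarray(ttubule, dtype=float), RESAMPLE_STEP_NM)
    if mask.all():
        mid = _polyline_arc_midpoint(np.asarray(jsr[0], dtype=float))
        idx = int(np.argmin(np.hypot(pts[:, 0] - mid[0], pts[:, 1] - mid[1])))
    else:
        start, length = _largest_circular_run(mask)
        idx = (start + length // 2) % len(mask)
    point, direction = np.asarray(zline[0], float), np.asarray(zline[1], float)
    return _point_line_distance(pts[idx], point, direction)


def analyze_scene(scene: EMScene, d_max_nm: float = DEFAULT_D_MAX_NM) -> DyadGeometryMetrics:
    """Bundle the three dyad morphometrics for one traced scene."""
    circ = circularity(scene.ttubule)
    cr = coupling_ratio(scene.ttubule, scene.jsr, d_max_nm)
    jz: float | None = None
    if cr > 0 and scene.zline is not None:
        jz = junction_z_distance(scene.ttubule, scene.jsr, scene.zline, d_max_nm)
    return DyadGeometryMetrics(circularity=circ, coupling_ratio=cr,
                               junction_z_distance_nm=jz)
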