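"""Synthetic traced EM dyad cross-sections with exact geometric truth.

A T-tubule cross-section is an n-vertex polygon on an ellipse; the jSR is a
polyline offset outward by the dyadic cleft (~12 nm) covering a contiguous
arc of a configured fraction of the perimeter; the Z-line is an infinite
line at a configured perpendicular distance from the junction (arc
midpoint of the jSR footprint).  The whole scene is randomly rotated and
translated so analyses cannot rely on axis alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..dyadgeom import EMScene, _shoelace_area, _perimeter


@dataclass(frozen=True)
class EMSimConfig:
    ellipse_semi_axes_nm: tuple[float, float] = (250.0, 200.0)  # (a, b), a >= b
    n_vertices: int = 256
    jsr_arc_fraction: float = 0.6
    cleft_nm: float = 12.0
    zline_distance_nm: float = 20.0

    def __post_init__(self) -> None:
        a, b = self.ellipse_semi_axes_nm
        if not (a >= b > 0):
            raise ValueError("ellipse semi-axes must satisfy a >= b > 0")
        if not 0.0 <= self.jsr_arc_fraction <= 1.0:
            raise ValueError("jsr_arc_fraction must be in [0, 1]")
        if self.cleft_nm <= 0:
            raise ValueError("cleft_nm must be positive")
        if self.n_vertices < 16:
            raise ValueError("n_vertices must be >= 16")
        if self.zline_distance_nm < 0:
            raise ValueError("zline_distance_nm must be non-negative")


def _ellipse_points(a: float, b: float, t: np.ndarray) -> np.ndarray:
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def _ellipse_outward_normals(a: float, b: float, t: np.ndarray) -> np.ndarray:
    # gradient of (x/a)^2 + (y/b)^2 at the boundary point
    n = np.column_stack([np.cos(t) / a, np.sin(t) / b])
    n /= np.hypot(n[:, 0], n[:, 1])[:, None]
    return n


def make_em_scene(config: EMSimConfig, seed: int) -> EMScene:
    """Build one traced dyad scene; ground truth is stored in scene metadata."""
    a, b = config.ellipse_semi_axes_nm
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    t_vert = np.linspace(0.0, 2.0 * math.pi, config.n_vertices, endpoint=False)
    poly = _ellipse_points(a, b, t_vert)

    # fine parametrisation for arc-length bookkeeping
    t_fine = np.linspace(0.0, 2.0 * math.pi, 20000, endpoint=False)
    pts_fine = _ellipse_points(a, b, t_fine)
    d = np.diff(np.vstack([pts_fine, pts_fine[:1]]), axis=0)
    ds = np.hypot(d[:, 0], d[:, 1])
    s_fine = np.concatenate([[0.0], np.cumsum(ds)])[:-1]
    perimeter = float(ds.sum())

    jsr: list[np.ndarray] = []
    s_mid = None
    if config.jsr_arc_fraction > 0:
        arc_len = config.jsr_arc_fraction * perimeter
        s0 = rng.uniform(0.0, perimeter)
        s_mid = (s0 + arc_len / 2.0) % perimeter
        n_samp = max(int(arc_len / 2.0), 8)  # ~2 nm sampling along the jSR
        s_arc = (s0 + np.linspace(0.0, arc_len, n_samp)) % perimeter
        t_arc = np.interp(s_arc, s_fine, t_fine)
        base = _ellipse_points(a, b, t_arc)
        normals = _ellipse_outward_normals(a, b, t_arc)
        jsr = [base + config.cleft_nm * normals]

    if s_mid is None:
        s_mid = 0.0
    t_mid = float(np.interp(s_mid, s_fine, t_fine))
    p_mid = _ellipse_points(a, b, np.array([t_mid]))[0]
    n_mid = _ellipse_outward_normals(a, b, np.array([t_mid]))[0]
    z_point = p_mid + config.zline_distance_nm * n_mid
    z_dir = np.array([-n_mid[1], n_mid[0]])  # perpendicular to the normal

    # random rigid motion of the whole scene
    phi = rng.uniform(0.0, 2.0 * math.pi)
    rot = np.array([[math.cos(phi), -math.sin(phi)],
                    [math.sin(phi), math.cos(phi)]])
    shift = rng.uniform(-500.0, 500.0, size=2)

    def xform(p: np.ndarray) -> np.ndarray:
        return p @ rot.T + shift

    poly_t = xform(poly)
    truth = {
        "circularity": 4.0 * math.pi * _shoelace_area(poly_t) / _perimeter(poly_t) ** 2,
        "coupling_ratio": config.jsr_arc_fraction,
        "junction_z_distance_nm": config.zline_distance_nm,
        "cleft_nm": config.cleft_nm,
        "ellipse_semi_axes_nm": [a, b],
    }
    return EMScene(
        ttubule=poly_t,
        jsr=[xform(p) for p in jsr],
        zline=(xform(z_point[None, :])[0], (rot @ z_dir)),
        truth=truth,
    )
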