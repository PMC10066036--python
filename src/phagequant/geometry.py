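"""Spherocylinder (capsule) geometry for rod-shaped bacteria.

Rod-shaped mycobacteria are modelled as 2-D capsules: a rectangle of
half-width ``r`` around a midline segment, closed by two semicircular pole
caps.  The closed boundary is parameterised by arclength, which lets the
simulator place phage particles and membrane label at defined positions
(pole caps, septum arc, lateral wall) and lets the quantification code
anchor perpendicular sampling lines at equal arclength spacing.

Coordinate convention: images are row-major with origin at the top-left and
pixel centres at integer coordinates; all polylines here are continuous
``(x=col, y=row)`` coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as _MplPath

__all__ = ["Capsule", "polyline_length", "resample_closed", "points_in_polygon"]


def _rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counter-clockwise in x,y)."""
    return np.array([-v[1], v[0]])


@dataclass(frozen=True)
class Capsule:
    """A 2-D spherocylinder defined by its midline segment and half-width.

    Parameters
    ----------
    p0, p1
        Midline endpoints in continuous ``(x, y)`` pixel coordinates.
        ``p0`` is, by convention, the end flagged as the *old* pole by the
        caller; the geometry itself is symmetric.
    radius
        Half-width in pixels (cap radius).
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    radius: float

    # -- derived scalars ---------------------------------------------------
    @property
    def midline_length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    @property
    def length(self) -> float:
        """Pole-to-pole length (midline plus both caps)."""
        return self.midline_length + 2.0 * self.radius

    @property
    def width(self) -> float:
        return 2.0 * self.radius

    @property
    def circumference(self) -> float:
        return 2.0 * self.midline_length + 2.0 * np.pi * self.radius

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from p0 to p1."""
        d = np.asarray(self.p1, float) - np.asarray(self.p0, float)
        n = np.hypot(*d)
        if n == 0:
            raise ValueError("degenerate capsule: p0 == p1")
        return d / n

    @property
    def orientation(self) -> float:
        u = self.axis
        return float(np.arctan2(u[1], u[0]))

    @property
    def centroid(self) -> np.ndarray:
        return (np.asarray(self.p0, float) + np.asarray(self.p1, float)) / 2.0

    # -- arclength parameterisation ---------------------------------------
    # The boundary starts at p0 + r*n (n = axis rotated +90deg), runs along
    # side A to p1 + r*n, around the p1 cap through the tip p1 + r*u, back
    # along side B, and around the p0 cap to the start.
    def _segments(self):
        u = self.axis
        n = _rot90(u)
        r = self.radius
        ell = self.midline_length
        return u, n, r, ell

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Boundary point(s) at arclength ``s`` (wrapped modulo circumference)."""
        u, n, r, ell = self._segments()
        p0 = np.asarray(self.p0, float)
        p1 = np.asarray(self.p1, float)
        C = self.circumference
        s = np.atleast_1d(np.asarray(s, float)) % C
        cap = np.pi * r
        out = np.empty((s.size, 2))
        # side A: [0, ell)
        m = s < ell
        out[m] = p0 + n * r + np.outer(s[m], u)
        # cap at p1: [ell, ell + pi r)
        m = (s >= ell) & (s < ell + cap)
        ang = (s[m] - ell) / r  # 0 at +n, pi at -n, passing through +u
        out[m] = p1 + np.outer(np.cos(ang), n * r) + np.outer(np.sin(ang), u * r)
        # side B: [ell + pi r, 2 ell + pi r)
        m = (s >= ell + cap) & (s < 2 * ell + cap)
        out[m] = p1 - n * r - np.outer(s[m] - ell - cap, u)
        # cap at p0: rest
        m = s >= 2 * ell + cap
        ang = (s[m] - 2 * ell - cap) / r
        out[m] = p0 + np.outer(-np.cos(ang), n * r) + np.outer(-np.sin(ang), u * r)
        return out if out.shape[0] > 1 else out[0]

    # -- region arcs -------------------------------------------------------
    def cap_arcs(self) -> dict[str, tuple[float, float]]:
        """Arclength intervals of the two semicircular pole caps.

        Keys are ``"p0"`` and ``"p1"``; each value is a half-open interval
        ``(start, stop)`` in arclength units.
        """
        _, _, r, ell = self._segments()
        cap = np.pi * r
        return {"p1": (ell, ell + cap), "p0": (2 * ell + cap, 2 * ell + 2 * cap)}

    def septum_arcs(self, half_width_px: float = 1.0) -> list[tuple[float, float]]:
        """Arclength intervals within ``half_width_px`` of the mid-cell plane.

        Two short arcs, one on each lateral side.  Empty if the midline is
        shorter than the septum band.
        """
        _, _, r, ell = self._segments()
        cap = np.pi * r
        h = min(half_width_px, ell / 2.0)
        if h <= 0:
            return []
        mid_a = ell / 2.0
        mid_b = ell + cap + ell / 2.0
        return [(mid_a - h, mid_a + h), (mid_b - h, mid_b + h)]

    def classify_arclength(self, s: float, septum: bool = False,
                           old_pole: str = "p0") -> str:
        """Site class of a boundary arclength: old_pole/new_pole/septum/lateral."""
        C = self.circumference
        s = float(s) % C
        if septum:
            for a, b in self.septum_arcs():
                if a <= s < b:
                    return "septum"
        caps = self.cap_arcs()
        for key, (a, b) in caps.items():
            if a <= s < b:
                return "old_pole" if key == old_pole else "new_pole"
        return "lateral"

    # -- polyline export ---------------------------------------------------
    def boundary_polyline(self, max_step: float = 0.5) -> np.ndarray:
        """Closed boundary polyline sampled at arc steps <= ``max_step`` px.

        The first point is repeated as the last (explicit closure).
        """
        C = self.circumference
        n = max(int(np.ceil(C / max_step)), 8)
        s = np.linspace(0.0, C, n, endpoint=False)
        pts = self.point_at(s)
        return np.vstack([pts, pts[:1]])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True for points inside the capsule (distance to midline <= r)."""
        pts = np.atleast_2d(np.asarray(points, float))
        p0 = np.asarray(self.p0, float)
        u = self.axis
        ell = self.midline_length
        d = pts - p0
        t = np.clip(d @ u, 0.0, ell)
        closest = p0 + np.outer(t, u)
        return np.hypot(*(pts - closest).T) <= self.radius

    def distance_to(self, other: "Capsule") -> float:
        """Minimum distance between the two midline segments."""
        return _segment_distance(np.asarray(self.p0, float), np.asarray(self.p1, float),
                                 np.asarray(other.p0, float), np.asarray(other.p1, float))


def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between segments a0-a1 and b0-b1 (dense sampling-free)."""

    def point_seg(p, q0, q1):
        d = q1 - q0
        L2 = d @ d
        if L2 == 0:
            return float(np.hypot(*(p - q0)))
        t = np.clip((p - q0) @ d / L2, 0.0, 1.0)
        return float(np.hypot(*(p - (q0 + t * d))))

    # segments intersect?
    def ccw(p, q, r):
        return (r[1] - p[1]) * (q[0] - p[0]) - (q[1] - p[1]) * (r[0] - p[0])

    if (ccw(a0, a1, b0) * ccw(a0, a1, b1) < 0) and (ccw(b0, b1, a0) * ccw(b0, b1, a1) < 0):
        return 0.0
    return min(point_seg(a0, b0, b1), point_seg(a1, b0, b1),
               point_seg(b0, a0, a1), point_seg(b1, a0, a1))


def polyline_length(poly: np.ndarray) -> float:
    """Total length of a polyline given as (N, 2) vertices."""
    d = np.diff(np.asarray(poly, float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def resample_closed(poly: np.ndarray, arclengths: np.ndarray) -> np.ndarray:
    """Sample a closed polyline at the given arclengths (linear interpolation).

    ``poly`` must be closed (first vertex == last).  Arclengths are wrapped
    modulo the total perimeter.
    """
    poly = np.asarray(poly, float)
    seg = np.hypot(*np.diff(poly, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate polyline")
    s = np.asarray(arclengths, float) % total
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.column_stack([x, y])


def points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorised point-in-polygon test for a closed polyline."""
    return _MplPath(np.asarray(poly, float)).contains_points(np.atleast_2d(points))
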