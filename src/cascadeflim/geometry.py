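"""Planar triangle geometry of a three-fluorophore system.

Three pairwise FRET separations define a triangle (three points are always
coplanar); vertex angles follow from the law of cosines.  Vertices are named
N, M, C after the first (donor), middle and last barrel of the construct, so
the side order is (r_NM, r_MC, r_NC) and the opening angle at M is the angle
between the two arms the middle fluorophore forms with its neighbours.

Separations are treated as chromophore-to-chromophore point distances; barrel
radii are not added or subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleGeometryError, InvalidParameterError

__all__ = ["TriangleGeometry", "triangle_from_separations", "embed_triangle", "compare_geometry"]

_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class TriangleGeometry:
    """Triangle of three labelled vertices: sides (r_NM, r_MC, r_NC) in nm and
    the interior angle at each vertex in degrees (summing to 180)."""

    vertices: tuple[str, str, str]
    sides_nm: tuple[float, float, float]
    angles_deg: tuple[float, float, float]
    degenerate: bool = False

    def angle_at(self, label: str) -> float:
        return self.angles_deg[self.vertices.index(label)]

    def side_between(self, a: str, b: str) -> float:
        pairs = {
            frozenset(self.vertices[:2]): self.sides_nm[0],
            frozenset(self.vertices[1:]): self.sides_nm[1],
            frozenset((self.vertices[0], self.vertices[2])): self.sides_nm[2],
        }
        return pairs[frozenset((a, b))]


def _angle(opposite: float, s1: float, s2: float) -> float:
    """Interior angle (deg) opposite `opposite`, between sides s1 and s2."""
    cosv = (s1 * s1 + s2 * s2 - opposite * opposite) / (2.0 * s1 * s2)
    return math.degrees(math.acos(min(1.0, max(-1.0, cosv))))


def triangle_from_separations(
    r_NM: float,
    r_MC: float,
    r_NC: float,
    vertices: tuple[str, str, str] = ("N", "M", "C"),
) -> TriangleGeometry:
    """Build the triangle from its three pairwise separations (nm).

    Raises :class:`InfeasibleGeometryError` naming the violating side when the
    triangle inequality fails (expected for noisy FRET distances); collinear
    inputs yield a degenerate triangle with 0/180 degree angles and a flag.
    """
    sides = (r_NM, r_MC, r_NC)
    if any(s <= 0 for s in sides):
        raise InvalidParameterError("all separations must be positive")
    names = {r_NM: f"{vertices[0]}-{vertices[1]}", r_MC: f"{vertices[1]}-{vertices[2]}",
             r_NC: f"{vertices[0]}-{vertices[2]}"}
    for s, (o1, o2) in ((r_NM, (r_MC, r_NC)), (r_MC, (r_NM, r_NC)), (r_NC, (r_NM, r_MC))):
        if s > o1 + o2 + _COLLINEAR_TOL * s:
            raise InfeasibleGeometryError(
                f"side {names[s]} = {s} nm exceeds the sum of the other two "
                f"({o1} + {o2} nm); separations do not form a triangle"
            )
    degenerate = any(
        abs(s - (o1 + o2)) <= _COLLINEAR_TOL * max(s, 1.0)
        for s, (o1, o2) in ((r_NM, (r_MC, r_NC)), (r_MC, (r_NM, r_NC)), (r_NC, (r_NM, r_MC)))
    )
    # angle at N is opposite r_MC, at M opposite r_NC, at C opposite r_NM
    angles = (
        _angle(r_MC, r_NM, r_NC),
        _angle(r_NC, r_NM, r_MC),
        _angle(r_NM, r_MC, r_NC),
    )
    # enforce exact 180-degree closure against acos rounding
    total = sum(angles)
    angles = tuple(a * 180.0 / total for a in angles)
    return TriangleGeometry(vertices=vertices, sides_nm=sides, angles_deg=angles, degenerate=degenerate)


def embed_triangle(geom: TriangleGeometry) -> dict[str, np.ndarray]:
    """Planar coordinates (nm): N at the origin, M on the +x axis, C above."""
    r_NM, r_MC, r_NC = geom.sides_nm
    x_C = (r_NC**2 + r_NM**2 - r_MC**2) / (2.0 * r_NM)
    y_C = math.sqrt(max(r_NC**2 - x_C**2, 0.0))
    n, m, c = geom.vertices
    return {
        n: np.array([0.0, 0.0]),
        m: np.array([r_NM, 0.0]),
        c: np.array([x_C, y_C]),
    }


def compare_geometry(
    measured: TriangleGeometry,
    reference_coords_nm: dict[str, np.ndarray],
) -> dict:
    """Signed differences (measured - reference) per side (nm) and angle (deg).

    ``reference_coords_nm`` maps each vertex label to 2-D or 3-D coordinates
    (e.g. barrel centroids of a structural model).
    """
    labels = measured.vertices
    missing = [l for l in labels if l not in reference_coords_nm]
    if missing:
        raise InvalidParameterError(f"reference coordinates missing labels: {missing}")
    pts = {l: np.asarray(reference_coords_nm[l], dtype=float) for l in labels}

    def dist(a, b):
        return float(np.linalg.norm(pts[a] - pts[b]))

    n, m, c = labels
    ref_tri = triangle_from_separations(dist(n, m), dist(m, c), dist(n, c), vertices=labels)
    report = {
        "sides_nm": {},
        "angles_deg": {},
        "reference_sides_nm": {},
        "reference_angles_deg": {},
    }
    side_labels = (f"{n}-{m}", f"{m}-{c}", f"{n}-{c}")
    for i, lab in enumerate(side_labels):
        report["reference_sides_nm"][lab] = ref_tri.sides_nm[i]
        report["sides_nm"][lab] = measured.sides_nm[i] - ref_tri.sides_nm[i]
    for i, lab in enumerate(labels):
        report["reference_angles_deg"][lab] = ref_tri.angles_deg[i]
        report["angles_deg"][lab] = measured.angles_deg[i] - ref_tri.angles_deg[i]
    return report
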