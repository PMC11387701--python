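"""Geometric primitives the morphology measurements are built from.

Everything here operates on plain ``(n, 2)`` arrays in the canonical frame
(y superior, lateral = +x) unless noted.  The three primitives are the
least-squares femoral-head circle, axes (pelvic horizontal reference,
femoral head-neck axis, femoral shaft axis), and vector angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .landmarks import HipPair, HipSchema, LandmarkSet

__all__ = [
    "Circle",
    "Axis",
    "DegenerateGeometryError",
    "MissingLandmarkError",
    "fit_circle",
    "angle_deg",
    "pelvic_reference_axis",
    "neck_axis",
    "shaft_axis",
]

#: Condition-number threshold above which the circle-fit normal equations are
#: treated as degenerate (collinear points).
COLLINEARITY_CONDITION_LIMIT = 1e12


class DegenerateGeometryError(ValueError):
    """Raised when the input geometry does not determine the requested object."""


class MissingLandmarkError(ValueError):
    """Raised when required landmarks (segments) are absent or too few."""


@dataclass(frozen=True)
class Circle:
    """A fitted circle: center, radius, and the rms orthogonal residual."""

    center: np.ndarray
    radius: float
    rms: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if not self.radius > 0:
            raise DegenerateGeometryError(f"circle radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class Axis:
    """A line through ``point`` with a unit ``direction`` and a semantic label."""

    point: np.ndarray
    direction: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise DegenerateGeometryError("axis direction must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / norm)


def fit_circle(points: np.ndarray) -> Circle:
    """Least-squares circle through >= 3 non-collinear points.

    Algebraic (Kasa) initialization followed by geometric refinement that
    minimizes orthogonal distances; exact (to solver tolerance ~1e-12) on
    points that lie on a true circle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 2-D points")

    # Kasa: x^2 + y^2 = a x + b y + c, linear in (a, b, c).
    shift = pts.mean(axis=0)  # center data for conditioning
    q = pts - shift
    A = np.column_stack([q, np.ones(len(q))])
    rhs = (q**2).sum(axis=1)
    gram = A.T @ A
    if np.linalg.cond(gram) > COLLINEARITY_CONDITION_LIMIT:
        raise DegenerateGeometryError("points are (nearly) collinear; no unique circle")
    a, b, c = np.linalg.solve(gram, A.T @ rhs)
    cx, cy = a / 2.0, b / 2.0
    r0 = float(np.sqrt(c + cx**2 + cy**2))

    def residual(params: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(q - params[:2], axis=1)
        return d - params[2]

    sol = least_squares(
        residual, x0=[cx, cy, r0], method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    cx, cy, r = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return Circle(center=np.array([cx, cy]) + shift, radius=float(r), rms=rms)


def angle_deg(u: np.ndarray, v: np.ndarray, signed: bool = False) -> float:
    """Angle between two non-zero vectors, in degrees.

    Unsigned: in [0, 180].  Signed: in (-180, 180], positive counter-clockwise
    (u rotated CCW onto v is positive) in the canonical frame.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise DegenerateGeometryError("angle of a zero vector is undefined")
    cross = u[0] * v[1] - u[1] * v[0]
    dot = float(u @ v)
    ang = float(np.degrees(np.arctan2(cross, dot)))
    if signed:
        return 180.0 if ang == -180.0 else ang
    return abs(ang)


def pelvic_reference_axis(
    pair: Optional[HipPair],
    schema: HipSchema,
    fallback: Optional[Axis] = None,
) -> Axis:
    """Horizontal reference line of the pelvis, in image coordinates.

    Runs through the caudal teardrop landmarks of the two hips, direction
    normalized left-hip -> right-hip.  With a single hip the caller must
    supply an explicit fallback axis (e.g. the image horizontal), which is
    returned unchanged.
    """
    if pair is None:
        if fallback is not None:
            return fallback
        raise MissingLandmarkError(
            "reference line unavailable: need both hips or an explicit fallback axis"
        )
    t_left = schema.point(pair.left.points, "TEARDROP_CAUDAL")
    t_right = schema.point(pair.right.points, "TEARDROP_CAUDAL")
    direction = t_right - t_left
    if np.linalg.norm(direction) == 0:
        raise DegenerateGeometryError("teardrop landmarks coincide")
    return Axis(point=(t_left + t_right) / 2.0, direction=direction, label="pelvic_horizontal")


def _paired_segments(lset: LandmarkSet, schema: HipSchema, role_a: str, role_b: str):
    seg_a = schema.segment(lset.points, role_a)
    seg_b = schema.segment(lset.points, role_b)
    n = min(len(seg_a), len(seg_b))
    return seg_a[:n], seg_b[:n]


def neck_axis(lset: LandmarkSet, schema: HipSchema, head: Circle) -> Axis:
    """Femoral head-neck axis (canonical frame).

    Runs from the fitted head center through the midpoint of the narrowest
    neck cross-section, where cross-sections pair the i-th lateral with the
    i-th medial neck landmark.  Direction points from head center toward the
    neck.  A single pair is allowed (degenerate but deterministic).
    """
    lat, med = _paired_segments(lset, schema, "NECK_LATERAL", "NECK_MEDIAL")
    if len(lat) == 0:
        raise MissingLandmarkError("neck segments are empty; head-neck axis unavailable")
    widths = np.linalg.norm(lat - med, axis=1)
    mid = (lat[np.argmin(widths)] + med[np.argmin(widths)]) / 2.0
    direction = mid - head.center
    if np.linalg.norm(direction) == 0:
        raise DegenerateGeometryError("neck midpoint coincides with head center")
    return Axis(point=head.center, direction=direction, label="neck")


def shaft_axis(lset: LandmarkSet, schema: HipSchema) -> Axis:
    """Longitudinal axis of the femoral shaft (canonical frame).

    Least-squares line through the midpoints of paired (lateral_i, medial_i)
    shaft landmarks; direction points distally.  Shaft landmarks are ordered
    proximal -> distal, which fixes the distal orientation.  Fewer than two
    pairs means too little shaft is depicted: the neck-shaft angle must then
    be reported missing, not zero.
    """
    lat, med = _paired_segments(lset, schema, "SHAFT_LATERAL", "SHAFT_MEDIAL")
    if len(lat) < 2:
        raise MissingLandmarkError("insufficient femoral shaft")
    mids = (lat + med) / 2.0
    centroid = mids.mean(axis=0)
    # Principal direction of the midpoints (total least squares).
    _, _, vt = np.linalg.svd(mids - centroid)
    direction = vt[0]
    if direction @ (mids[-1] - mids[0]) < 0:
        direction = -direction
    return Axis(point=centroid, direction=direction, label="shaft")
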