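"""The eight radiographic hip-morphology measurements.

Given a canonicalized landmark set (y superior, lateral = +x) and a pelvic
horizontal reference axis, this module computes:

========  =================================  ======================================
symbol    name                               quantifies
========  =================================  ======================================
ADR       acetabular depth-width ratio       acetabular depth (A/B * 1000)
mAI       modified acetabular index          acetabular roof inclination (Tonnis)
AA        alpha angle                        head-neck junction asphericity (cam)
WCEA      Wiberg center edge angle           weight-bearing (sourcil) coverage
LCEA      lateral center edge angle          bony acetabular coverage (pincer)
EI        extrusion index                    % of head width uncovered laterally
NSA       neck-shaft angle                   coxa vara / valga
TIR       triangular index ratio             head asphericity at the 0.5r station
========  =================================  ======================================

All are angles (degrees) or ratios, hence invariant under translation,
rotation, and uniform scaling of the landmarks, and — because right hips are
mirrored into the canonical frame — under left/right mirroring.

Sign conventions: mAI is positive when the lateral roof edge lies superior
to the medial sourcil (up-sloping roof); WCEA/LCEA are positive when the
target point lies lateral to the vertical through the head center and
negative when medial (possible in dysplastic hips).

Individual measurements that cannot be computed (e.g. NSA when too little
femoral shaft is depicted) are reported *missing with a reason*; they never
abort the rest of the set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import (
    Axis,
    Circle,
    DegenerateGeometryError,
    MissingLandmarkError,
    angle_deg,
    fit_circle,
    neck_axis,
    pelvic_reference_axis,
    shaft_axis,
)
from .landmarks import HipPair, HipSchema, LandmarkSet, canonical_transform, canonicalize

__all__ = [
    "MeasurementSet",
    "MeasureOptions",
    "MEASUREMENT_NAMES",
    "ANGLE_MEASUREMENTS",
    "RATIO_MEASUREMENTS",
    "measure_adr",
    "measure_mai",
    "measure_alpha",
    "measure_wcea",
    "measure_lcea",
    "measure_ei",
    "measure_nsa",
    "measure_tir",
    "measure_all",
    "measure_pair",
    "measurements_frame",
    "canonical_reference",
]

MEASUREMENT_NAMES = (
    "adr",
    "mai_deg",
    "alpha_deg",
    "wcea_deg",
    "lcea_deg",
    "ei_pct",
    "nsa_deg",
    "tir",
)

#: Measurements expressed in degrees vs dimensionless ratios/percentages —
#: drives the systematic-error rule in the agreement statistics.
ANGLE_MEASUREMENTS = ("mai_deg", "alpha_deg", "wcea_deg", "lcea_deg", "nsa_deg")
RATIO_MEASUREMENTS = ("adr", "ei_pct", "tir")


@dataclass(frozen=True)
class MeasureOptions:
    """Tunable measurement parameters.

    ``alpha_departure_tol`` is the relative radial tolerance epsilon for the
    alpha point: the contour is considered to have left the head circle at
    the first landmark farther than ``r * (1 + epsilon)`` from the center.
    To stay robust against annotation noise the effective tolerance is
    ``max(epsilon * r, alpha_noise_factor * rms)`` where rms is the head
    circle-fit residual: on noiseless landmarks this reduces to epsilon
    exactly, on noisy ones it keeps the departure threshold above the noise
    floor.  ``alpha_search_window_deg`` bounds the departure search to the
    superior-lateral sector (signed angle from the neck axis).
    ``tir_orientation`` selects the reported ratio orientation, ``d_over_r``
    (default: > 1 means aspherical) or ``r_over_d``.
    """

    alpha_departure_tol: float = 0.01
    alpha_noise_factor: float = 3.0
    alpha_search_window_deg: float = 105.0
    tir_orientation: str = "d_over_r"
    tir_station: float = 0.5  # station along the neck axis, in units of r


@dataclass
class MeasurementSet:
    """The eight named measurements for one hip; each value or missing-with-reason."""

    adr: Optional[float] = None
    mai_deg: Optional[float] = None
    alpha_deg: Optional[float] = None
    wcea_deg: Optional[float] = None
    lcea_deg: Optional[float] = None
    ei_pct: Optional[float] = None
    nsa_deg: Optional[float] = None
    tir: Optional[float] = None
    missing: dict[str, str] = field(default_factory=dict)
    alpha_point: Optional[np.ndarray] = None
    head: Optional[Circle] = None
    image_id: str = ""
    side: str = ""

    def value(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in MEASUREMENT_NAMES}


# ---------------------------------------------------------------------------
# Frame helpers
# ---------------------------------------------------------------------------

def canonical_reference(ref: Optional[Axis], side: str) -> Axis:
    """Express an image-frame pelvic reference axis in a hip's canonical frame.

    ``ref`` follows the left-hip-teardrop -> right-hip-teardrop direction
    convention, so a hip's lateral direction (away from the contralateral
    hip) is ``-ref.direction`` for left hips and ``+ref.direction`` for
    right hips — purely anatomical, independent of how the image is
    oriented.  ``None`` yields the default assumption of an exactly
    image-horizontal pelvis in standard AP orientation (lateral = +x after
    canonicalization).
    """
    if ref is None:
        return Axis(point=(0.0, 0.0), direction=(1.0, 0.0), label="pelvic_horizontal")
    lateral_img = -ref.direction if side == "left" else ref.direction
    d = canonical_transform(side) @ lateral_img
    return Axis(point=(0.0, 0.0), direction=d, label="pelvic_horizontal")


def _frame_vectors(ref: Axis) -> tuple[np.ndarray, np.ndarray]:
    """Lateral unit vector u (the reference direction) and superior unit v."""
    u = ref.direction
    v = np.array([-u[1], u[0]])  # 90 deg CCW: superior for lateral u
    return u, v


def _fit_head(lset: LandmarkSet, schema: HipSchema) -> Circle:
    return fit_circle(schema.segment(lset.points, "HEAD_CONTOUR"))


# ---------------------------------------------------------------------------
# Acetabular measurements
# ---------------------------------------------------------------------------

def measure_adr(lset: LandmarkSet, schema: HipSchema, ref: Axis) -> float:
    """Acetabular depth-width ratio, A/B * 1000.

    B (width) runs from the most lateral bony edge of the acetabulum to the
    most caudal point of the teardrop; A (depth) is the perpendicular
    distance from the most medial sourcil point to that line.
    """
    e = schema.point(lset.points, "ACETAB_LATERAL_EDGE")
    t = schema.point(lset.points, "TEARDROP_CAUDAL")
    m = schema.point(lset.points, "SOURCIL_MEDIAL")
    w = t - e
    b = float(np.linalg.norm(w))
    if b == 0:
        raise DegenerateGeometryError("acetabular width is zero (edge and teardrop coincide)")
    d = m - e
    a = abs(w[0] * d[1] - w[1] * d[0]) / b
    return a / b * 1000.0


def measure_mai(lset: LandmarkSet, schema: HipSchema, ref: Axis) -> float:
    """Modified acetabular index: inclination of the sourcil roof line.

    Signed angle between the pelvic reference and the line from the medial
    sourcil to the lateral bony edge; positive for an up-sloping roof.
    """
    u, v = _frame_vectors(ref)
    e = schema.point(lset.points, "ACETAB_LATERAL_EDGE")
    m = schema.point(lset.points, "SOURCIL_MEDIAL")
    d = e - m
    if np.linalg.norm(d) == 0:
        raise DegenerateGeometryError("sourcil and lateral edge coincide")
    return float(np.degrees(np.arctan2(d @ v, d @ u)))


def _center_edge_angle(target: np.ndarray, head: Circle, ref: Axis) -> float:
    u, v = _frame_vectors(ref)
    p = target - head.center
    if np.linalg.norm(p) == 0:
        raise DegenerateGeometryError("target point coincides with the head center")
    # Positive when lateral to the vertical through the head center.
    return float(np.degrees(np.arctan2(p @ u, p @ v)))


def measure_wcea(lset: LandmarkSet, schema: HipSchema, ref: Axis, head: Circle) -> float:
    """Wiberg center edge angle: head center to the lateral sourcil point."""
    return _center_edge_angle(schema.point(lset.points, "SOURCIL_LATERAL"), head, ref)


def measure_lcea(lset: LandmarkSet, schema: HipSchema, ref: Axis, head: Circle) -> float:
    """Lateral center edge angle: head center to the lateral bony acetabular edge."""
    return _center_edge_angle(schema.point(lset.points, "ACETAB_LATERAL_EDGE"), head, ref)


def measure_ei(lset: LandmarkSet, schema: HipSchema, ref: Axis, head: Circle) -> float:
    """Extrusion index: percent of the femoral head width uncovered laterally.

    Distances are taken along the reference direction; the lateral and medial
    head extremes come from the fitted circle (robust to landmark sampling
    density): A = uncovered width lateral to the bony edge, B = covered
    width, EI = A/(A+B) * 100.
    """
    u, _ = _frame_vectors(ref)
    e_u = float(schema.point(lset.points, "ACETAB_LATERAL_EDGE") @ u)
    c_u = float(head.center @ u)
    a = max(0.0, (c_u + head.radius) - e_u)
    b = e_u - (c_u - head.radius)
    if a + b <= 0:
        raise DegenerateGeometryError("degenerate head/edge configuration for EI")
    return min(100.0, a / (a + b) * 100.0)


# ---------------------------------------------------------------------------
# Head-neck measurements
# ---------------------------------------------------------------------------

def _superior_profile(lset: LandmarkSet, schema: HipSchema, include_neck: bool) -> np.ndarray:
    """Concatenated superior bony profile, ordered head -> neck."""
    parts = [
        schema.segment(lset.points, "HEAD_CONTOUR"),
        schema.segment(lset.points, "HEADNECK_SUPERIOR_CONTOUR"),
    ]
    if include_neck:
        parts.append(schema.segment(lset.points, "NECK_LATERAL"))
    return np.concatenate([p for p in parts if len(p)])


def _neckward_start(profile: np.ndarray, head: Circle, nax: Axis) -> int:
    """Index of the profile point farthest from the neck (traversal start)."""
    return int(np.argmin((profile - head.center) @ nax.direction))


def measure_alpha(
    lset: LandmarkSet,
    schema: HipSchema,
    head: Circle,
    nax: Axis,
    opts: MeasureOptions = MeasureOptions(),
) -> tuple[float, np.ndarray]:
    """Alpha angle and the alpha point.

    Traverses the superior-lateral part of the head + head-neck contour from
    the point farthest from the neck toward the neck; the alpha point is the
    first landmark leaving the best-fitting circle, i.e. farther than
    ``r + max(epsilon * r, noise_factor * rms)`` from the head center.  If
    no landmark exceeds the tolerance the last superior-contour landmark is
    used.  The angle is the unsigned angle at the head center between the
    neck axis and the line to the alpha point.
    """
    profile = _superior_profile(lset, schema, include_neck=False)
    if len(profile) == 0:
        raise MissingLandmarkError("no superior contour landmarks")
    rel = profile - head.center
    n = nax.direction
    # Signed angle from the neck axis; positive on the superior-lateral side.
    psi = np.degrees(np.arctan2(n[0] * rel[:, 1] - n[1] * rel[:, 0], rel @ n))
    in_window = (psi >= 0.0) & (psi <= opts.alpha_search_window_deg)
    candidates = np.nonzero(in_window)[0]
    if len(candidates) == 0:
        raise MissingLandmarkError("no superior-lateral contour landmarks")
    start = candidates[np.argmax(psi[candidates])]
    limit = head.radius + max(
        opts.alpha_departure_tol * head.radius, opts.alpha_noise_factor * head.rms
    )
    alpha_point = profile[candidates[-1]]
    for i in candidates[candidates >= start]:
        if np.linalg.norm(rel[i]) > limit:
            alpha_point = profile[i]
            break
    aa = angle_deg(n, alpha_point - head.center, signed=False)
    return aa, np.asarray(alpha_point, dtype=float)


def measure_nsa(lset: LandmarkSet, schema: HipSchema, nax: Axis) -> float:
    """Neck-shaft angle: head-directed neck vector vs distally-directed shaft axis."""
    shaft = shaft_axis(lset, schema)
    return angle_deg(-nax.direction, shaft.direction, signed=False)


def measure_tir(
    lset: LandmarkSet,
    schema: HipSchema,
    head: Circle,
    nax: Axis,
    opts: MeasureOptions = MeasureOptions(),
) -> float:
    """Triangular index ratio at the 0.5r station along the head-neck axis.

    The station line is perpendicular to the neck axis through the point
    ``center + 0.5 r * neck_direction``.  S is the first crossing of the
    superior bony profile (head contour, head-neck junction, lateral neck —
    traversed from the point farthest from the neck) with that line, found
    by linear interpolation along the piecewise-linear contour; with
    d = |S - center|, the default orientation reports d/r, so TIR > 1 means
    the contour lies outside the head circle at the station (aspherical
    head, cam morphology).
    """
    profile = _superior_profile(lset, schema, include_neck=True)
    if len(profile) < 2:
        raise MissingLandmarkError("no superior contour landmarks")
    start = _neckward_start(profile, head, nax)
    s = (profile - head.center) @ nax.direction - opts.tir_station * head.radius
    for i in range(start, len(profile) - 1):
        if s[i] == 0.0:
            point = profile[i]
        elif s[i] * s[i + 1] < 0:
            t = s[i] / (s[i] - s[i + 1])
            point = profile[i] + t * (profile[i + 1] - profile[i])
        else:
            continue
        d = float(np.linalg.norm(point - head.center))
        if opts.tir_orientation == "r_over_d":
            return head.radius / d
        return d / head.radius
    raise MissingLandmarkError("no contour intersection at the 0.5r station")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def measure_all(
    lset: LandmarkSet,
    schema: HipSchema,
    ref: Optional[Axis] = None,
    opts: MeasureOptions = MeasureOptions(),
) -> MeasurementSet:
    """Compute all eight measurements for one hip.

    ``lset`` may be in either frame (image sets are canonicalized first);
    ``ref`` is the pelvic reference axis in the *same* frame as ``lset``
    (``None`` assumes an image-horizontal pelvis).  Individual failures are
    recorded as missing values with reasons and never abort the set.
    """
    lset.validate(schema)
    if lset.frame == "image":
        cref = canonical_reference(ref, lset.side)
        cset = canonicalize(lset)
    else:
        cref = ref if ref is not None else canonical_reference(None, lset.side)
        cset = lset

    result = MeasurementSet(image_id=lset.image_id, side=lset.side)

    def attempt(name: str, fn):
        try:
            return fn()
        except (DegenerateGeometryError, MissingLandmarkError) as exc:
            result.missing[name] = str(exc)
            return None

    head = attempt("head", lambda: _fit_head(cset, schema))
    result.head = head
    nax = None
    if head is not None:
        nax = attempt("neck_axis", lambda: neck_axis(cset, schema, head))

    result.adr = attempt("adr", lambda: measure_adr(cset, schema, cref))
    result.mai_deg = attempt("mai_deg", lambda: measure_mai(cset, schema, cref))
    if head is not None:
        result.wcea_deg = attempt("wcea_deg", lambda: measure_wcea(cset, schema, cref, head))
        result.lcea_deg = attempt("lcea_deg", lambda: measure_lcea(cset, schema, cref, head))
        result.ei_pct = attempt("ei_pct", lambda: measure_ei(cset, schema, cref, head))
    else:
        for name in ("wcea_deg", "lcea_deg", "ei_pct"):
            result.missing[name] = "head circle fit unavailable"
    if head is not None and nax is not None:
        alpha = attempt("alpha_deg", lambda: measure_alpha(cset, schema, head, nax, opts))
        if alpha is not None:
            result.alpha_deg, result.alpha_point = alpha
        result.nsa_deg = attempt("nsa_deg", lambda: measure_nsa(cset, schema, nax))
        result.tir = attempt("tir", lambda: measure_tir(cset, schema, head, nax, opts))
    else:
        reason = "head-neck axis unavailable"
        for name in ("alpha_deg", "nsa_deg", "tir"):
            result.missing[name] = reason
    return result


def measure_pair(
    pair: HipPair,
    schema: HipSchema,
    opts: MeasureOptions = MeasureOptions(),
) -> dict[str, MeasurementSet]:
    """Measure both hips of a pelvic image using its own teardrop reference line."""
    ref = pelvic_reference_axis(pair, schema)
    return {
        "left": measure_all(pair.left, schema, ref, opts),
        "right": measure_all(pair.right, schema, ref, opts),
    }


def measurements_frame(sets: list[MeasurementSet]) -> pd.DataFrame:
    """Batch MeasurementSets into a DataFrame (one row per hip, NaN = missing)."""
    rows = []
    for m in sets:
        row: dict = {"image_id": m.image_id, "side": m.side}
        row.update({k: (np.nan if v is None else v) for k, v in m.as_dict().items()})
        row["missing_reasons"] = "; ".join(f"{k}: {v}" for k, v in m.missing.items())
        row["head_fit_rms"] = m.head.rms if m.head is not None else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df.index = [f"{r.image_id}:{r.side}" for r in df.itertuples()]
        df.index.name = "hip_id"
    return df
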