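"""Parametric generator of pelvis/hip landmark sets with known ground truth.

The generator constructs, in the canonical frame, a hip whose landmarks
realize prescribed target values of the directly-constructible measurements
(alpha angle, Wiberg and lateral center edge angles, modified acetabular
index, acetabular depth-width ratio, neck-shaft angle) *exactly*, and whose
extrusion index and triangular index ratio follow analytically from the
construction.  Together with an isotropic Gaussian landmark-jitter model of
observer/annotation variability, this makes every other module testable
without radiographs: generate -> jitter -> measure -> compare closes the
loop against known truth.

Construction sketch (left hip, head center at the origin, radius r):

- the femoral head contour lies exactly on the circle of radius r;
- the superior head-neck contour leaves the circle at polar angle
  ``target_alpha_deg`` from the head-neck axis, with a radial cam blend that
  exceeds the alpha-point departure tolerance at the very first landmark
  beyond the alpha station (so the measured alpha angle is exact up to
  contour quantization, half a contour spacing);
- neck and shaft landmark pairs are symmetric about their axes, so the
  measured head-neck and shaft axes — and hence the neck-shaft angle — are
  exact;
- acetabular landmarks (teardrop, sourcil edges, lateral bony edge) are
  placed to realize the target center edge angles, roof inclination, and
  depth-width ratio exactly, with the teardrops of the two hips at equal
  height so the pelvic reference line is exactly horizontal;
- the contralateral hip is the mirror image.

Target combinations that cannot be realized (e.g. a lateral bony edge forced
medial to the sourcil edge) raise :class:`ConstructionError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import Circle
from .landmarks import HipPair, HipSchema, LandmarkSet, default_schema, write_pts
from .morphometry import (
    MeasureOptions,
    MeasurementSet,
    measure_pair,
    measurements_frame,
)

__all__ = [
    "HipSpec",
    "StudySpec",
    "StudyResult",
    "ConstructionError",
    "generate_hip",
    "jitter",
    "simulate_study",
    "write_study",
]


class ConstructionError(ValueError):
    """Raised when a target combination is geometrically infeasible."""


# Geometry constants of the construction, in units of the head radius r.
_R_LATERAL_EDGE = 1.15   # distance head center -> lateral bony acetabular edge
_R_SOURCIL_LAT = 1.12    # distance head center -> lateral sourcil point
_SOURCIL_MEDIAL_X = -0.55  # lateral (+x) coordinate of the medial sourcil
_TEARDROP_Y = -0.20      # superior (+y) coordinate of the caudal teardrop
_INFERIOR_JUNCTION_DEG = 75.0  # head arc end on the inferior-medial side
_DEPARTURE_STEP = 0.015  # initial relative radial departure of the cam blend
_CAM_SLOPE = 0.45        # radial departure growth per radian beyond alpha
_NECK_S = (1.05, 1.60)   # neck span along the axis
_NECK_HALFWIDTH = 0.42   # minimum neck half-width
_NECK_FLARE = 0.35       # quadratic half-width growth
_NECK_WAIST = 1.20       # axis station of the narrowest cross-section
_SHAFT_BASE = 1.60       # shaft centerline origin along the neck axis
_SHAFT_SPAN = (0.25, 1.60)
_SHAFT_HALFWIDTH = 0.35
_PELVIS_CENTER = np.array([500.0, 400.0])  # image px
_HIP_OFFSET = 250.0      # head-center distance from the pelvis midline, px


@dataclass(frozen=True)
class HipSpec:
    """Ground-truth morphology targets for one generated hip.

    Angles in degrees, the depth-width ratio on its conventional x1000
    scale.  ``neck_axis_tilt_deg`` is the inclination of the head-neck axis
    from the image vertical toward lateral.  EI and TIR are emergent: they
    are derived from the construction, not prescribed.
    """

    head_radius: float = 100.0
    target_alpha_deg: float = 47.0
    target_lcea_deg: float = 31.0
    target_wcea_deg: float = 26.0
    target_mai_deg: float = 5.0
    target_adr: float = 290.0
    target_nsa_deg: float = 130.0
    neck_axis_tilt_deg: float = 40.0
    include_shaft: bool = True
    contour_spacing_deg: float = 2.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        checks = [
            ("head_radius", self.head_radius, 1.0, np.inf),
            ("target_alpha_deg", self.target_alpha_deg, 40.0, 100.0),
            ("target_lcea_deg", self.target_lcea_deg, -10.0, 60.0),
            ("target_wcea_deg", self.target_wcea_deg, -10.0, 60.0),
            ("target_nsa_deg", self.target_nsa_deg, 100.0, 160.0),
            ("neck_axis_tilt_deg", self.neck_axis_tilt_deg, 20.0, 60.0),
            ("contour_spacing_deg", self.contour_spacing_deg, 0.25, 8.0),
            ("target_adr", self.target_adr, 100.0, 500.0),
            ("target_mai_deg", self.target_mai_deg, -10.0, 30.0),
        ]
        for name, value, lo, hi in checks:
            if not (lo <= value <= hi):
                raise ConstructionError(f"{name}={value} outside representable range [{lo}, {hi}]")


def _unit(deg: float) -> np.ndarray:
    rad = np.radians(deg)
    return np.array([np.cos(rad), np.sin(rad)])


def _rot90(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _cam_radius(r: float, alpha_deg: float, psi_deg: np.ndarray | float) -> np.ndarray | float:
    """Radial profile of the head-neck blend beyond the alpha station."""
    return r * (1.0 + _DEPARTURE_STEP + _CAM_SLOPE * np.radians(alpha_deg - psi_deg))


def _build_canonical(spec: HipSpec) -> tuple[np.ndarray, MeasurementSet, HipSchema]:
    """Construct the left-hip landmark array in the canonical frame (head at origin)."""
    r = spec.head_radius
    alpha = spec.target_alpha_deg
    tau = spec.neck_axis_tilt_deg
    spacing = spec.contour_spacing_deg
    schema = default_schema(include_shaft=spec.include_shaft)

    # Head-neck axis (head center -> neck) and its superior-lateral normal.
    n = np.array([np.sin(np.radians(tau)), -np.cos(np.radians(tau))])
    m = _rot90(n)

    def on_profile(psi_deg: float, rho: float) -> np.ndarray:
        rad = np.radians(psi_deg)
        return rho * (np.cos(rad) * n + np.sin(rad) * m)

    pts = np.zeros((schema.n_points, 2))

    # --- femoral head contour: exactly on the circle -----------------------
    h0, h1 = schema.segments["HEAD_CONTOUR"]
    n_head = h1 - h0
    arc = 360.0 - _INFERIOR_JUNCTION_DEG - alpha
    psi_head = -_INFERIOR_JUNCTION_DEG - np.arange(n_head) * arc / (n_head - 1)
    for i, psi in enumerate(psi_head):
        pts[h0 + i] = on_profile(psi, r)

    # --- superior head-neck contour: cam blend past the alpha station ------
    j0, j1 = schema.segments["HEADNECK_SUPERIOR_CONTOUR"]
    psi_junction = alpha - spacing * (0.5 + np.arange(j1 - j0))
    for i, psi in enumerate(psi_junction):
        pts[j0 + i] = on_profile(psi, float(_cam_radius(r, alpha, psi)))

    # --- neck: paired edges symmetric about the axis ------------------------
    nl0, nl1 = schema.segments["NECK_LATERAL"]
    nm0, nm1 = schema.segments["NECK_MEDIAL"]
    s_neck = np.linspace(_NECK_S[0], _NECK_S[1], nl1 - nl0) * r

    def halfwidth(s: np.ndarray) -> np.ndarray:
        return _NECK_HALFWIDTH * r + _NECK_FLARE / r * (s - _NECK_WAIST * r) ** 2

    w = halfwidth(s_neck)
    for i, (s, wi) in enumerate(zip(s_neck, w)):
        pts[nl0 + i] = s * n + wi * m
        pts[nm0 + i] = s * n - wi * m

    # --- shaft: paired edges about a centerline realizing the NSA ----------
    nsa_truth: Optional[float] = None
    if spec.include_shaft:
        neckvec = -n  # neck-base -> head center
        rad = np.radians(spec.target_nsa_deg)
        rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
        d_shaft = rot @ neckvec  # distally directed
        e = _rot90(d_shaft)
        base = _SHAFT_BASE * r * n
        sl0, sl1 = schema.segments["SHAFT_LATERAL"]
        sm0, _ = schema.segments["SHAFT_MEDIAL"]
        t_shaft = np.linspace(_SHAFT_SPAN[0], _SHAFT_SPAN[1], sl1 - sl0) * r
        for i, t in enumerate(t_shaft):
            center = base + t * d_shaft
            pts[sl0 + i] = center + _SHAFT_HALFWIDTH * r * e
            pts[sm0 + i] = center - _SHAFT_HALFWIDTH * r * e
        nsa_truth = spec.target_nsa_deg

    # --- acetabulum ---------------------------------------------------------
    edge = _R_LATERAL_EDGE * r * np.array(
        [np.sin(np.radians(spec.target_lcea_deg)), np.cos(np.radians(spec.target_lcea_deg))]
    )
    sourcil_lat = _R_SOURCIL_LAT * r * np.array(
        [np.sin(np.radians(spec.target_wcea_deg)), np.cos(np.radians(spec.target_wcea_deg))]
    )
    if edge[0] <= sourcil_lat[0]:
        raise ConstructionError(
            "lateral bony edge forced medial to the sourcil edge "
            f"(LCEA {spec.target_lcea_deg} vs WCEA {spec.target_wcea_deg})"
        )
    mai_rad = np.radians(spec.target_mai_deg)
    length = (edge[0] - _SOURCIL_MEDIAL_X * r) / np.cos(mai_rad)
    sourcil_med = edge - length * np.array([np.cos(mai_rad), np.sin(mai_rad)])

    q = spec.target_adr / 1000.0
    d = sourcil_med - edge

    def depth(gamma: float) -> float:
        return abs(np.sin(gamma) * d[0] - np.cos(gamma) * d[1])

    def teardrop_height_error(gamma: float) -> float:
        return edge[1] - depth(gamma) / q * np.sin(gamma) - _TEARDROP_Y * r

    lo, hi = np.radians(5.0), np.radians(75.0)
    if teardrop_height_error(lo) * teardrop_height_error(hi) > 0:
        raise ConstructionError(
            f"no acetabular width line realizes ADR {spec.target_adr} with this geometry"
        )
    gamma = brentq(teardrop_height_error, lo, hi, xtol=1e-12)
    b_len = depth(gamma) / q
    teardrop = edge - b_len * np.array([np.cos(gamma), np.sin(gamma)])
    if teardrop[0] >= sourcil_med[0]:
        raise ConstructionError("teardrop not medial to the sourcil; ADR target infeasible")

    i_t = schema.points["TEARDROP_CAUDAL"]
    i_m = schema.points["SOURCIL_MEDIAL"]
    i_s = schema.points["SOURCIL_LATERAL"]
    i_e = schema.points["ACETAB_LATERAL_EDGE"]
    for start, stop, a, b in (
        (i_t, i_m, teardrop, sourcil_med),
        (i_m, i_s, sourcil_med, sourcil_lat),
        (i_s, i_e, sourcil_lat, edge),
    ):
        steps = stop - start
        for j in range(steps + 1):
            pts[start + j] = a + (b - a) * j / steps

    # --- analytic ground truth ----------------------------------------------
    a_ei = max(0.0, r - edge[0])
    b_ei = edge[0] + r
    truth = MeasurementSet(
        adr=spec.target_adr,
        mai_deg=spec.target_mai_deg,
        alpha_deg=alpha,
        wcea_deg=spec.target_wcea_deg,
        lcea_deg=spec.target_lcea_deg,
        ei_pct=min(100.0, 100.0 * a_ei / (a_ei + b_ei)),
        nsa_deg=nsa_truth,
        tir=_truth_tir(spec),
        head=Circle(center=np.zeros(2), radius=r),
    )
    if nsa_truth is None:
        truth.missing["nsa_deg"] = "insufficient femoral shaft"
    return pts, truth, schema


def _truth_tir(spec: HipSpec, station: float = 0.5) -> float:
    """TIR of the continuous construction (independent of landmark sampling)."""
    r = spec.head_radius
    alpha = spec.target_alpha_deg
    station_s = station * r
    cos_alpha = np.cos(np.radians(alpha))
    if cos_alpha >= station:
        return 1.0  # the circle itself crosses the station line
    psi_end = alpha - spec.contour_spacing_deg * 9.5

    def axial(psi: float) -> float:
        return float(_cam_radius(r, alpha, psi)) * np.cos(np.radians(psi)) - station_s

    if axial(alpha) >= 0:
        # The crossing sits on the radial step at the alpha station itself:
        # along that segment s = rho * cos(alpha), so d = 0.5 r / cos(alpha).
        return station / cos_alpha
    if axial(psi_end) > 0:
        psi_cross = brentq(axial, psi_end, alpha, xtol=1e-12)
        return float(_cam_radius(r, alpha, psi_cross)) / r
    # Crossing on the connector between the blend end and the neck edge.
    rho_end = float(_cam_radius(r, alpha, psi_end))
    rad = np.radians(psi_end)
    p1 = np.array([rho_end * np.cos(rad), rho_end * np.sin(rad)])  # (axis, normal) coords
    s0 = _NECK_S[0] * r
    w0 = _NECK_HALFWIDTH * r + _NECK_FLARE / r * (s0 - _NECK_WAIST * r) ** 2
    p2 = np.array([s0, w0])
    t = (station_s - p1[0]) / (p2[0] - p1[0])
    return float(np.linalg.norm(p1 + t * (p2 - p1))) / r


def generate_hip(spec: HipSpec, image_id: str = "synthetic") -> tuple[HipPair, MeasurementSet]:
    """Generate a pelvic landmark pair realizing ``spec``, plus its ground truth.

    The returned hips are in image coordinates; the ground truth describes
    the *left* hip (the right hip is its exact mirror, so the truth applies
    to both).  Use ``default_schema(include_shaft=spec.include_shaft)`` to
    measure the result.
    """
    pts, truth, _ = _build_canonical(spec)
    cx, cy = _PELVIS_CENTER

    left_img = np.column_stack([pts[:, 0] + cx + _HIP_OFFSET, cy - pts[:, 1]])
    right_img = np.column_stack([cx - _HIP_OFFSET - pts[:, 0], cy - pts[:, 1]])
    left = LandmarkSet(left_img, side="left", image_id=image_id)
    right = LandmarkSet(right_img, side="right", image_id=image_id)
    truth.image_id = image_id
    truth.side = "left"
    return HipPair(left=left, right=right), truth


def jitter(lset: LandmarkSet, sd: float, seed: int | Sequence[int]) -> LandmarkSet:
    """Isotropic Gaussian displacement of every landmark; sd=0 is the identity."""
    if sd < 0:
        raise ValueError("jitter sd must be >= 0")
    if sd == 0:
        return lset
    rng = np.random.default_rng(seed)
    return replace(lset, points=lset.points + rng.normal(0.0, sd, lset.points.shape))


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

#: Per-target uniform sampling ranges emulating the morphological spread of a
#: general-population radiograph sample (WCEA is drawn as LCEA minus a margin).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "target_alpha_deg": (42.0, 78.0),
    "target_lcea_deg": (18.0, 45.0),
    "wcea_margin_deg": (2.0, 8.0),
    "target_mai_deg": (-2.0, 14.0),
    "target_adr": (230.0, 330.0),
    "target_nsa_deg": (115.0, 145.0),
    "neck_axis_tilt_deg": (36.0, 44.0),
}


@dataclass(frozen=True)
class StudySpec:
    """A reliability-study design: n hips measured by observers over rounds.

    Each observer is a ``(jitter_sd_px, seed)`` pair; every observer x round
    applies an independent jitter draw to the same underlying hips,
    emulating repeated annotation of the same radiographs.
    """

    n_hips: int = 30
    observers: tuple[tuple[float, int], ...] = ((1.5, 11), (1.5, 22))
    rounds: int = 2
    seed: int = 0
    head_radius: float = 100.0
    contour_spacing_deg: float = 2.0
    include_shaft: bool = True
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        if self.n_hips < 1:
            raise ValueError("n_hips must be >= 1")
        for sd, _ in self.observers:
            if sd < 0:
                raise ValueError("jitter sd must be >= 0")


@dataclass
class StudyResult:
    specs: list[HipSpec]
    pairs: list[HipPair]
    truth: pd.DataFrame
    batches: dict[str, pd.DataFrame]
    schema: HipSchema


def _sample_spec(study: StudySpec, rng: np.random.Generator) -> HipSpec:
    rg = study.ranges
    for _ in range(50):
        lcea = rng.uniform(*rg["target_lcea_deg"])
        spec = HipSpec(
            head_radius=study.head_radius,
            target_alpha_deg=rng.uniform(*rg["target_alpha_deg"]),
            target_lcea_deg=lcea,
            target_wcea_deg=lcea - rng.uniform(*rg["wcea_margin_deg"]),
            target_mai_deg=rng.uniform(*rg["target_mai_deg"]),
            target_adr=rng.uniform(*rg["target_adr"]),
            target_nsa_deg=rng.uniform(*rg["target_nsa_deg"]),
            neck_axis_tilt_deg=rng.uniform(*rg["neck_axis_tilt_deg"]),
            include_shaft=study.include_shaft,
            contour_spacing_deg=study.contour_spacing_deg,
        )
        try:
            _build_canonical(spec)
        except ConstructionError:
            continue
        return spec
    raise ConstructionError("could not sample a feasible hip spec in 50 tries")


def simulate_study(study: StudySpec, opts: MeasureOptions = MeasureOptions()) -> StudyResult:
    """Generate a study: hips, per observer x round jittered measurements.

    Returns measurement batches (one frame per observer x round, keyed
    ``obs<i>_round<j>``) aligned by hip id and ready for
    :func:`hipmorph.agreement.reliability_report`, plus the ground truth.
    """
    rng = np.random.default_rng(study.seed)
    schema = default_schema(include_shaft=study.include_shaft)
    specs, pairs, truths = [], [], []
    for idx in range(study.n_hips):
        spec = _sample_spec(study, rng)
        pair, truth = generate_hip(spec, image_id=f"hip{idx:03d}")
        specs.append(spec)
        pairs.append(pair)
        truths.append(truth)

    batches: dict[str, pd.DataFrame] = {}
    for obs_idx, (sd, obs_seed) in enumerate(study.observers):
        for round_idx in range(study.rounds):
            sets = []
            for hip_idx, pair in enumerate(pairs):
                seed = [study.seed, obs_seed, round_idx, hip_idx]
                noisy = HipPair(
                    left=jitter(pair.left, sd, seed + [0]),
                    right=jitter(pair.right, sd, seed + [1]),
                )
                sets.append(measure_pair(noisy, schema, opts)["left"])
            batches[f"obs{obs_idx + 1}_round{round_idx + 1}"] = measurements_frame(sets)
    return StudyResult(
        specs=specs,
        pairs=pairs,
        truth=measurements_frame(truths),
        batches=batches,
        schema=schema,
    )


def write_study(study_result: StudyResult, out_dir: str | Path) -> None:
    """Write the unjittered ``.pts`` fixtures and a ground-truth manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in study_result.pairs:
        write_pts(pair.left, out / f"{pair.image_id}_left.pts")
        write_pts(pair.right, out / f"{pair.image_id}_right.pts")
    manifest = study_result.truth.copy()
    manifest.round(6).to_csv(out / "ground_truth.csv")
    study_result.schema.to_yaml(out / "schema.yaml")
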