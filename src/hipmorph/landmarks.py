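"""Landmark data model, anatomical schema, and point-set file I/O.

A hip is represented by an ordered set of 2-D landmarks placed on the bony
outline of the proximal femur and acetabulum on an AP pelvic radiograph
(BoneFinder-style annotation, 80 points by default).  Which landmark plays
which anatomical role (teardrop, sourcil edges, head contour, ...) is not
hard-coded: it is described by a :class:`HipSchema`, packaged as an editable
YAML file, so the pipeline works with any annotation protocol that provides
the required roles.

Coordinate conventions
----------------------
Files store *image* coordinates: x to the right, y **down** (pixel
convention).  All geometry downstream runs in a *canonical* frame: y points
superior (up) and the lateral direction is +x for every hip, which means
right-side hips are mirrored about a vertical axis.  Use :func:`canonicalize`
to convert; measurements on a left hip and its mirrored right-hip
counterpart are then bitwise-comparable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "LandmarkSet",
    "HipSchema",
    "HipPair",
    "SchemaError",
    "LandmarkParseError",
    "POINT_ROLES",
    "SEGMENT_ROLES",
    "default_schema",
    "read_pts",
    "write_pts",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "canonicalize",
]

#: Roles that resolve to a single landmark index.
POINT_ROLES = (
    "TEARDROP_CAUDAL",
    "ACETAB_LATERAL_EDGE",
    "SOURCIL_MEDIAL",
    "SOURCIL_LATERAL",
    "FEMORAL_HEAD_APEX",
)

#: Roles that resolve to a contiguous half-open index range [start, stop).
SEGMENT_ROLES = (
    "HEAD_CONTOUR",
    "HEADNECK_SUPERIOR_CONTOUR",
    "NECK_MEDIAL",
    "NECK_LATERAL",
    "SHAFT_MEDIAL",
    "SHAFT_LATERAL",
)


class SchemaError(ValueError):
    """Raised when a schema or a landmark set violates the schema contract."""


class LandmarkParseError(ValueError):
    """Raised for malformed landmark files; message names the offending line."""


@dataclass(frozen=True)
class HipSchema:
    """Maps semantic anatomical roles to landmark indices (0-based).

    ``points`` maps a point role to one index; ``segments`` maps a segment
    role to a half-open ``(start, stop)`` range.  Shaft segments may be
    absent (or shorter than 2 points), in which case the neck-shaft angle is
    reported missing rather than computed.
    """

    n_points: int
    points: dict[str, int]
    segments: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise SchemaError("n_points must be positive")
        for role, idx in self.points.items():
            if not (0 <= idx < self.n_points):
                raise SchemaError(f"point role {role} index {idx} out of range")
        for role in POINT_ROLES:
            if role not in self.points:
                raise SchemaError(f"missing point role {role}")
        spans = []
        for role, (start, stop) in self.segments.items():
            if not (0 <= start < stop <= self.n_points):
                raise SchemaError(f"segment role {role} range ({start}, {stop}) invalid")
            spans.append((start, stop, role))
        spans.sort()
        for (s1, e1, r1), (s2, e2, r2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise SchemaError(f"segments {r1} and {r2} overlap")
        for role in ("HEAD_CONTOUR", "HEADNECK_SUPERIOR_CONTOUR", "NECK_MEDIAL", "NECK_LATERAL"):
            if role not in self.segments:
                raise SchemaError(f"missing segment role {role}")
        h0, h1 = self.segments["HEAD_CONTOUR"]
        if h1 - h0 < 5:
            raise SchemaError("HEAD_CONTOUR needs >= 5 points for a circle fit")

    def point(self, pts: np.ndarray, role: str) -> np.ndarray:
        return pts[self.points[role]]

    def segment(self, pts: np.ndarray, role: str) -> np.ndarray:
        if role not in self.segments:
            return pts[0:0]
        start, stop = self.segments[role]
        return pts[start:stop]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HipSchema":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "HipSchema":
        try:
            return cls(
                n_points=int(raw["n_points"]),
                points={k: int(v) for k, v in raw["points"].items()},
                segments={k: (int(v[0]), int(v[1])) for k, v in raw["segments"].items()},
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise SchemaError(f"malformed schema mapping: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "n_points": self.n_points,
            "points": dict(self.points),
            "segments": {k: list(v) for k, v in self.segments.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_schema(include_shaft: bool = True) -> HipSchema:
    """The packaged 80-point schema (68 points when the femoral shaft is absent)."""
    with resources.files("hipmorph.data").joinpath("default_schema.yaml").open("r") as fh:
        raw = yaml.safe_load(fh)
    schema = HipSchema._from_mapping(raw)
    if include_shaft:
        return schema
    segments = {k: v for k, v in schema.segments.items() if not k.startswith("SHAFT")}
    n = max([i + 1 for i in schema.points.values()] + [stop for _, stop in segments.values()])
    return HipSchema(n_points=n, points=dict(schema.points), segments=segments)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered 2-D landmarks for one hip.

    ``points`` is an ``(n, 2)`` float array.  ``frame`` records whether the
    coordinates are raw image pixels (y down) or the canonical measurement
    frame (y up, lateral = +x).  ``pixel_spacing`` (mm/px) is carried for
    provenance only: every measurement is an angle or a ratio, hence
    scale-free.
    """

    points: np.ndarray
    side: str
    image_id: str = ""
    pixel_spacing: Optional[float] = None
    frame: str = "image"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise SchemaError(f"points must be (n, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise SchemaError("landmark coordinates must all be finite")
        if self.side not in ("left", "right"):
            raise SchemaError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.frame not in ("image", "canonical"):
            raise SchemaError(f"frame must be 'image' or 'canonical', got {self.frame!r}")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def validate(self, schema: HipSchema) -> "LandmarkSet":
        if self.n_points != schema.n_points:
            raise SchemaError(
                f"landmark set has {self.n_points} points, schema expects {schema.n_points}"
            )
        return self


@dataclass(frozen=True)
class HipPair:
    """Left and right hip landmark sets from the same pelvic image.

    Only used to build the pelvic horizontal reference line (teardrop to
    teardrop), so both sides must share an image id.
    """

    left: LandmarkSet
    right: LandmarkSet

    def __post_init__(self) -> None:
        if self.left.side != "left" or self.right.side != "right":
            raise SchemaError("HipPair fields must hold a left and a right hip")
        if self.left.image_id != self.right.image_id:
            raise SchemaError(
                f"HipPair sides come from different images: "
                f"{self.left.image_id!r} vs {self.right.image_id!r}"
            )

    @property
    def image_id(self) -> str:
        return self.left.image_id


# ---------------------------------------------------------------------------
# File I/O: BoneFinder-style .pts and plain CSV
# ---------------------------------------------------------------------------

def read_pts(path: str | Path, schema: HipSchema, side: str) -> LandmarkSet:
    """Read a BoneFinder-style ``.pts`` file.

    Dialect: header lines ``version: <v>`` and ``n_points: <n>``, then a
    ``{`` ... ``}`` block with one ``x y`` pair per line, image coordinates.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    n_declared = None
    coords: list[tuple[float, float]] = []
    in_block = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("version:"):
            continue
        if stripped.startswith("n_points:"):
            try:
                n_declared = int(stripped.split(":", 1)[1])
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: bad n_points header") from exc
            continue
        if stripped == "{":
            in_block = True
            continue
        if stripped == "}":
            in_block = False
            continue
        if not in_block:
            raise LandmarkParseError(f"{path}:{lineno}: unexpected content outside {{...}} block")
        tokens = stripped.split()
        if len(tokens) != 2:
            raise LandmarkParseError(f"{path}:{lineno}: expected 'x y', got {stripped!r}")
        try:
            coords.append((float(tokens[0]), float(tokens[1])))
        except ValueError as exc:
            raise LandmarkParseError(f"{path}:{lineno}: non-numeric token in {stripped!r}") from exc
    if n_declared is None:
        raise LandmarkParseError(f"{path}: missing n_points header")
    if len(coords) != n_declared:
        raise LandmarkParseError(
            f"{path}: declared n_points {n_declared} but found {len(coords)} pairs"
        )
    if n_declared != schema.n_points:
        raise LandmarkParseError(
            f"{path}: file has {n_declared} points, schema expects {schema.n_points}"
        )
    return LandmarkSet(np.array(coords), side=side, image_id=path.stem).validate(schema)


def write_pts(lset: LandmarkSet, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("version: 1\n")
    buf.write(f"n_points: {lset.n_points}\n")
    buf.write("{\n")
    for x, y in lset.points:
        buf.write(f"{x:.6f} {y:.6f}\n")
    buf.write("}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_landmarks_csv(path: str | Path, schema: HipSchema, side: str) -> LandmarkSet:
    """Read landmarks from a CSV with columns ``index,x,y`` (0-based indices)."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    for col in ("index", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    idx = df["index"].to_numpy()
    if len(idx) != schema.n_points or sorted(idx.tolist()) != list(range(schema.n_points)):
        dupes = sorted({int(i) for i in idx if (idx == i).sum() > 1})
        if dupes:
            raise SchemaError(f"{path}: duplicated landmark indices {dupes}")
        raise SchemaError(
            f"{path}: indices must be 0..{schema.n_points - 1} each exactly once"
        )
    order = np.argsort(idx, kind="stable")
    pts = df[["x", "y"]].to_numpy(dtype=float)[order]
    return LandmarkSet(pts, side=side, image_id=path.stem).validate(schema)


def write_landmarks_csv(lset: LandmarkSet, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "index": np.arange(lset.n_points),
            "x": np.round(lset.points[:, 0], 6),
            "y": np.round(lset.points[:, 1], 6),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Canonical frame
# ---------------------------------------------------------------------------

def canonical_transform(side: str) -> np.ndarray:
    """Linear part of the image -> canonical map for the given side."""
    if side == "left":
        return np.diag([1.0, -1.0])
    return np.diag([-1.0, -1.0])


def canonicalize(lset: LandmarkSet) -> LandmarkSet:
    """Return the set in the canonical frame (y superior, lateral = +x).

    Left hips get a y-flip only; right hips are additionally mirrored about
    a vertical axis.  Idempotent: canonical sets are returned unchanged.
    """
    if lset.frame == "canonical":
        return lset
    pts = lset.points @ canonical_transform(lset.side).T
    return replace(lset, points=pts, frame="canonical")
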