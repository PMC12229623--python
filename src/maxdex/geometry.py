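"""Landmark geometry for the acromial index (AI) and its ultrasound analogue (mAX).

The acromial index is the ratio GA/GH of two medio-lateral distances: from a
glenoid reference line to the lateral acromion edge (GA) and to the lateral
edge of the humeral head (GH).  On MRI all three landmarks are visible and the
index is plain landmark arithmetic.  On ultrasound the glenoid is acoustically
inaccessible, so the modified index (mAX) replaces the glenoid line with the
*medial vertical tangent* of a circle extrapolated from the visible arc of the
humeral-head contour; its GH is therefore exactly the circle's diameter.

All computations happen in a canonical 2-D frame: coordinates in millimetres,
+x lateral, +y superior.  Right shoulders are mirrored about the y-axis first
(`normalize_laterality`) so that downstream math never branches on side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "Point2D",
    "CircleFit",
    "UltrasoundAnnotation",
    "MRILandmarks",
    "IndexMeasurement",
    "InputError",
    "DegenerateGeometryError",
    "ImplausibleGeometryError",
    "InvalidLandmarkError",
    "fit_circle",
    "vertical_tangents",
    "compute_max",
    "compute_ai",
    "normalize_laterality",
    "PATHOLOGICAL_THRESHOLD",
]

#: Default cut-off: indices strictly greater than this are classified
#: pathological (values > 0.7 are associated with rotator cuff tears).
PATHOLOGICAL_THRESHOLD = 0.7

_SIDES = ("left", "right")


class InputError(ValueError):
    """Malformed or insufficient input (wrong counts, labels, lengths)."""


class DegenerateGeometryError(ValueError):
    """Geometry does not determine a circle (e.g. collinear arc points)."""


class ImplausibleGeometryError(ValueError):
    """Landmarks produce an anatomically impossible configuration."""


class InvalidLandmarkError(ValueError):
    """Landmark coordinates violate the canonical-orientation invariants."""


@dataclass(frozen=True)
class Point2D:
    """A planar landmark in millimetres (+x lateral, +y superior)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"non-finite coordinates ({self.x}, {self.y})")

    def mirrored(self) -> "Point2D":
        return Point2D(-self.x, self.y)


@dataclass(frozen=True)
class CircleFit:
    """A least-squares circle: center, radius and goodness of fit."""

    center: Point2D
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DegenerateGeometryError(f"non-positive radius {self.radius}")
        if self.rms_residual < 0:
            raise InputError("negative rms_residual")
        if self.n_points < 3:
            raise InputError("a circle fit needs at least 3 points")


@dataclass(frozen=True)
class UltrasoundAnnotation:
    """One ultrasound measurement: humeral-head arc points + acromion edge.

    ``canonical`` records whether coordinates are already in the canonical
    (+x lateral) frame; raw right-shoulder annotations are not.
    """

    arc_points: tuple[Point2D, ...]
    acromion_edge: Point2D
    side: str
    patient_id: str
    rater_id: str
    repeat_index: int
    canonical: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "arc_points", tuple(self.arc_points))
        if self.side not in _SIDES:
            raise InputError(f"unknown side {self.side!r}; expected left/right")
        if len(self.arc_points) < 3:
            raise InputError("need at least 3 arc points")
        if any(p == self.acromion_edge for p in self.arc_points):
            raise InputError("acromion edge coincides with an arc point")


@dataclass(frozen=True)
class MRILandmarks:
    """Medio-lateral coordinates of the three MRI landmarks (mm)."""

    glenoid_x: float
    acromion_x: float
    humeral_lateral_x: float
    side: str
    patient_id: str
    rater_id: str
    repeat_index: int
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise InputError(f"unknown side {self.side!r}; expected left/right")
        for name in ("glenoid_x", "acromion_x", "humeral_lateral_x"):
            if not math.isfinite(getattr(self, name)):
                raise InputError(f"non-finite {name}")


@dataclass(frozen=True)
class IndexMeasurement:
    """One (patient, rater, repeat, modality) index value with classification.

    ``value == ga / gh`` always; classification uses a strict inequality, so a
    value of exactly 0.7 is normal.
    """

    patient_id: str
    rater_id: str
    repeat_index: int
    modality: str  # "US" or "MRI"
    value: float
    ga: float
    gh: float
    classification: str
    threshold: float = PATHOLOGICAL_THRESHOLD

    def __post_init__(self) -> None:
        if self.modality not in ("US", "MRI"):
            raise InputError(f"unknown modality {self.modality!r}")
        if self.gh <= 0:
            raise InvalidLandmarkError("GH must be positive")


def _classify(value: float, threshold: float) -> str:
    return "pathological" if value > threshold else "normal"


def normalize_laterality(obj):
    """Return ``obj`` in the canonical frame (+x lateral).

    Left-side inputs are canonical by convention; right-side inputs are
    mirrored about the y-axis.  Idempotent: an object already flagged
    canonical is returned unchanged.
    """
    if obj.canonical:
        return obj
    if isinstance(obj, UltrasoundAnnotation):
        if obj.side == "left":
            return replace(obj, canonical=True)
        return replace(
            obj,
            arc_points=tuple(p.mirrored() for p in obj.arc_points),
            acromion_edge=obj.acromion_edge.mirrored(),
            canonical=True,
        )
    if isinstance(obj, MRILandmarks):
        if obj.side == "left":
            return replace(obj, canonical=True)
        return replace(
            obj,
            glenoid_x=-obj.glenoid_x,
            acromion_x=-obj.acromion_x,
            humeral_lateral_x=-obj.humeral_lateral_x,
            canonical=True,
        )
    raise InputError(f"cannot normalize object of type {type(obj).__name__}")


def _kasa_fit(xy: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) circle fit: linear least squares on
    x² + y² = 2a·x + 2b·y + c.  Fast and exact for noiseless data; used as
    the initializer for the geometric refinement."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    rhs = x * x + y * y
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise DegenerateGeometryError(
            "arc points are collinear (or otherwise do not determine a circle)"
        )
    (a, b, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    r2 = c + a * a + b * b
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic fit produced non-positive radius")
    return float(a), float(b), float(math.sqrt(r2))


def _arc_span_deg(xy: np.ndarray, cx: float, cy: float) -> float:
    """Angular span (degrees) subtended by the points around the center:
    360° minus the largest angular gap."""
    ang = np.sort(np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2.0 * np.pi]]))
    return math.degrees(2.0 * np.pi - float(gaps.max()))


def fit_circle(points: Sequence[Point2D] | Iterable[Point2D]) -> CircleFit:
    """Fit a circle to ≥ 3 planar points by geometric least squares.

    The algebraic Kåsa solution initializes a Levenberg–Marquardt refinement
    of the orthogonal (geometric) distances, run to relative tolerance 1e-10
    (at most 100 iterations).  Raises :class:`InputError` for fewer than 3
    points and :class:`DegenerateGeometryError` for collinear configurations.
    A warning is logged when the subtended arc is below 60°, where the
    extrapolation to a full circle becomes ill-conditioned.
    """
    pts = list(points)
    if len(pts) < 3:
        raise InputError(f"need at least 3 points to fit a circle, got {len(pts)}")
    xy = np.array([[p.x, p.y] for p in pts], dtype=float)

    a, b, r = _kasa_fit(xy)

    def residuals(params: np.ndarray) -> np.ndarray:
        cx, cy, rad = params
        return np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) - rad

    sol = least_squares(
        residuals,
        x0=np.array([a, b, r]),
        method="lm",
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=100 * 3,
    )
    cx, cy, rad = sol.x
    res = residuals(sol.x)
    rms = float(np.sqrt(np.mean(res * res)))
    if rms < 1e-12:
        rms = 0.0

    span = _arc_span_deg(xy, cx, cy)
    if span < 60.0:
        logger.warning(
            "humeral-head arc spans only %.1f deg (< 60 deg): circle "
            "extrapolation is poorly conditioned",
            span,
        )
    return CircleFit(
        center=Point2D(float(cx), float(cy)),
        radius=float(rad),
        rms_residual=rms,
        n_points=len(pts),
    )


def vertical_tangents(circle: CircleFit, side: str = "left") -> tuple[float, float]:
    """Medio-lateral positions of the two vertical tangents of a circle.

    In the canonical frame the medial tangent sits at ``center.x - radius``
    and the lateral tangent at ``center.x + radius``; their separation is the
    diameter.  ``side`` is accepted for interface symmetry and validated, but
    the canonical frame makes the result side-independent.
    """
    if side not in _SIDES:
        raise InputError(f"unknown side {side!r}; expected left/right")
    return circle.center.x - circle.radius, circle.center.x + circle.radius


def compute_max(
    ann: UltrasoundAnnotation, threshold: float = PATHOLOGICAL_THRESHOLD
) -> IndexMeasurement:
    """Compute the ultrasound modified acromial index (mAX).

    Steps: normalize laterality; fit a circle to the visible humeral-head arc;
    drop vertical tangents; GA = distance from the medial tangent (the glenoid
    surrogate) to the acromion edge, GH = tangent separation = diameter;
    mAX = GA/GH.  Closed form: (AE.x − center.x + r) / (2r).
    """
    ann = normalize_laterality(ann)
    circle = fit_circle(ann.arc_points)
    x_medial, x_lateral = vertical_tangents(circle)
    ga = ann.acromion_edge.x - x_medial
    gh = x_lateral - x_medial
    if ga <= 0:
        raise ImplausibleGeometryError(
            "acromion edge lies medial to the glenoid surrogate (GA <= 0)"
        )
    value = ga / gh
    return IndexMeasurement(
        patient_id=ann.patient_id,
        rater_id=ann.rater_id,
        repeat_index=ann.repeat_index,
        modality="US",
        value=value,
        ga=ga,
        gh=gh,
        classification=_classify(value, threshold),
        threshold=threshold,
    )


def compute_ai(
    lm: MRILandmarks, threshold: float = PATHOLOGICAL_THRESHOLD
) -> IndexMeasurement:
    """Compute the MRI acromial index (AI) from the three landmark lines:
    GA = acromion − glenoid, GH = lateral humerus − glenoid, AI = GA/GH."""
    lm = normalize_laterality(lm)
    ga = lm.acromion_x - lm.glenoid_x
    gh = lm.humeral_lateral_x - lm.glenoid_x
    if gh <= 0:
        raise InvalidLandmarkError(
            "lateral humeral edge not lateral to the glenoid line (GH <= 0)"
        )
    value = ga / gh
    return IndexMeasurement(
        patient_id=lm.patient_id,
        rater_id=lm.rater_id,
        repeat_index=lm.repeat_index,
        modality="MRI",
        value=value,
        ga=ga,
        gh=gh,
        classification=_classify(value, threshold),
        threshold=threshold,
    )
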