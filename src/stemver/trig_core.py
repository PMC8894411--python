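"""Projection geometry of the femoral-component neck axis.

The orientation of the neck of a femoral THA component is described by the
angles of its projections onto the three orthogonal anatomical planes:

* **coronal inclination (CI)** — angle of the coronal (frontal) projection to
  the horizontal; low values read as varus, high as valgus;
* **sagittal inclination (SI)** — angle of the sagittal (lateral) projection
  to the vertical; large positive values read as ante-inclination;
* **transverse version (TV)** — angle of the transverse (axial) projection to
  the horizontal; positive is anteversion, negative retroversion.

With a right-handed frame whose ``x`` axis is medio-lateral (pointing to the
side the neck points to), ``y`` antero-posterior (anterior positive) and
``z`` vertical (superior positive), a unit neck axis ``(x, y, z)`` gives

    tan CI = z / x,    tan SI = y / z,    tan TV = y / x,

so the three angles are linked by the closed-form identity

    tan TV = tan SI * tan CI.

Any two of the three angles therefore determine the third; the functions
:func:`tv_from_ci_si`, :func:`ci_from_tv_si` and :func:`si_from_tv_ci` are
the three solved forms.  :func:`angles_from_axis` is the vector forward model
(robust ``atan2`` evaluation), and :func:`apparent_angles_nonorthogonal`
models the bias introduced when the sagittal view is not perpendicular to
the coronal one, as happens with imperfect biplanar radiography.

Angles at the interface are degrees throughout; radians are internal only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEGENERACY_TOL_DEG",
    "DegenerateInputError",
    "InconsistentAnglesError",
    "FrameConstructionError",
    "NeckAxis",
    "AnatomicalFrame",
    "OrientationAngles",
    "FemoralLandmarks",
    "PlaneMisalignment",
    "tv_from_ci_si",
    "ci_from_tv_si",
    "si_from_tv_ci",
    "angles_from_axis",
    "axis_from_angles",
    "mechanical_frame",
    "apparent_angles_nonorthogonal",
    "apparent_tv",
    "apparent_si",
]

#: Inputs closer than this (degrees) to a tangent pole or zero are rejected
#: rather than mapped to huge or undefined values.
DEGENERACY_TOL_DEG = 0.01


class DegenerateInputError(ValueError):
    """An angle or axis is too close to a configuration where a projection
    or a tangent collapses (accuracy of the closed forms degrades as angles
    approach 0 or 90 degrees)."""


class InconsistentAnglesError(ValueError):
    """An angle pair/triple violates the identity tan TV = tan SI * tan CI
    or implies an angle outside its physical range."""


class FrameConstructionError(ValueError):
    """Landmarks are degenerate (coincident or collinear) and do not define
    an anatomical frame."""


def _tan_deg(a: np.ndarray | float) -> np.ndarray | float:
    return np.tan(np.radians(a))


def _atan_deg(a: np.ndarray | float) -> np.ndarray | float:
    return np.degrees(np.arctan(a))


def _scalar_like(out: np.ndarray, *inputs) -> float | np.ndarray:
    """Return a python float when all inputs were scalars."""
    if all(np.ndim(x) == 0 for x in inputs):
        return float(out)
    return out


def _check_open(name: str, value: np.ndarray, lo: float, hi: float) -> None:
    if np.any(~np.isfinite(value)):
        raise DegenerateInputError(f"{name} contains non-finite values")
    if np.any(value <= lo) or np.any(value >= hi):
        raise DegenerateInputError(
            f"{name} must lie strictly inside ({lo}, {hi}) degrees "
            f"(margin {DEGENERACY_TOL_DEG} deg from tangent poles)"
        )


def tv_from_ci_si(ci, si):
    """Transverse version from coronal and sagittal inclination.

    ``TV = arctan(tan SI * tan CI)``, all in degrees.  ``ci`` must lie in
    (0, 90) and ``si`` in (-90, 90), both with a 0.01 deg margin from the
    poles.  Accepts scalars or arrays (broadcast).
    """
    ci_a = np.asarray(ci, dtype=float)
    si_a = np.asarray(si, dtype=float)
    _check_open("ci", ci_a, DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    _check_open("si", si_a, -90.0 + DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    tv = _atan_deg(_tan_deg(si_a) * _tan_deg(ci_a))
    return _scalar_like(tv, ci, si)


def ci_from_tv_si(tv, si):
    """Coronal inclination from transverse version and sagittal inclination.

    ``CI = arctan(tan TV / tan SI)``.  ``si`` must be bounded away from 0
    (the quotient is undefined there) and ``tv`` and ``si`` must share the
    same sign, otherwise the implied CI falls outside (0, 90).
    """
    tv_a = np.asarray(tv, dtype=float)
    si_a = np.asarray(si, dtype=float)
    _check_open("tv", tv_a, -90.0 + DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    _check_open("si", si_a, -90.0 + DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    if np.any(np.abs(si_a) <= DEGENERACY_TOL_DEG):
        raise DegenerateInputError(
            "si within 0.01 deg of 0: tan(tv)/tan(si) is undefined"
        )
    if np.any(tv_a * si_a <= 0.0):
        raise InconsistentAnglesError(
            "tv and si must be nonzero and share the same sign for a "
            "coronal inclination in (0, 90) degrees"
        )
    ci = _atan_deg(_tan_deg(tv_a) / _tan_deg(si_a))
    return _scalar_like(ci, tv, si)


def si_from_tv_ci(tv, ci):
    """Sagittal inclination from transverse version and coronal inclination.

    ``SI = arctan(tan TV / tan CI)``; the sign of the result equals the sign
    of ``tv``.
    """
    tv_a = np.asarray(tv, dtype=float)
    ci_a = np.asarray(ci, dtype=float)
    _check_open("tv", tv_a, -90.0 + DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    _check_open("ci", ci_a, DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    si = _atan_deg(_tan_deg(tv_a) / _tan_deg(ci_a))
    return _scalar_like(si, tv, ci)


@dataclass(frozen=True)
class NeckAxis:
    """Unit vector along the longitudinal axis of the prosthetic neck.

    Components follow the package convention: ``x`` medio-lateral (positive
    toward the side the neck points to, i.e. medially), ``y``
    antero-posterior (anterior positive), ``z`` vertical (superior
    positive).  The vector must be unit length to 1e-12 and point medially
    (``x > 0``); use :meth:`from_vector` to normalize arbitrary input.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        n = float(np.sqrt(self.x**2 + self.y**2 + self.z**2))
        if abs(n - 1.0) > 1e-12:
            raise ValueError(f"neck axis must be unit length, got norm {n!r}")
        if not self.x > 0.0:
            raise ValueError("neck axis must point medially (x > 0)")

    @classmethod
    def from_vector(cls, v) -> "NeckAxis":
        v = np.asarray(v, dtype=float)
        if v.shape != (3,):
            raise ValueError("expected a 3-vector")
        n = np.linalg.norm(v)
        if n == 0.0:
            raise ValueError("zero vector has no direction")
        v = v / n
        return cls(float(v[0]), float(v[1]), float(v[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal measurement frame.

    ``e_x`` medio-lateral horizontal, ``e_y`` antero-posterior, ``e_z``
    vertical; ``origin`` in mm.  Either the scanner frame (identity axes,
    the supine scanning position) or the mechanical femoral frame built by
    :func:`mechanical_frame` from bony landmarks.
    """

    origin: np.ndarray
    e_x: np.ndarray
    e_y: np.ndarray
    e_z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "e_x", "e_y", "e_z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        for name in ("e_x", "e_y", "e_z"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be unit length")
        pairs = [("e_x", "e_y"), ("e_x", "e_z"), ("e_y", "e_z")]
        for a, b in pairs:
            if abs(float(np.dot(getattr(self, a), getattr(self, b)))) > 1e-10:
                raise ValueError(f"{a} and {b} are not orthogonal")
        if np.max(np.abs(np.cross(self.e_x, self.e_y) - self.e_z)) > 1e-10:
            raise ValueError("frame is not right-handed (e_x x e_y != e_z)")

    @classmethod
    def scanner(cls, origin=(0.0, 0.0, 0.0)) -> "AnatomicalFrame":
        """The identity (scanning-position) frame."""
        return cls(
            origin=np.asarray(origin, dtype=float),
            e_x=np.array([1.0, 0.0, 0.0]),
            e_y=np.array([0.0, 1.0, 0.0]),
            e_z=np.array([0.0, 0.0, 1.0]),
        )

    def express(self, v) -> np.ndarray:
        """Coordinates of a direction vector ``v`` in this frame."""
        v = np.asarray(v, dtype=float)
        return np.array(
            [float(np.dot(self.e_x, v)), float(np.dot(self.e_y, v)), float(np.dot(self.e_z, v))]
        )


@dataclass(frozen=True)
class OrientationAngles:
    """A geometrically consistent (CI, SI, TV) triple in degrees.

    Construction validates the ranges (CI in (0, 90), SI and TV in
    (-90, 90)) and the projection identity ``tan TV = tan SI * tan CI``
    (relative tolerance 1e-9 in tangent space).  Noisy *measured* angle
    triples do not satisfy the identity and belong in plain table columns,
    not in this type.
    """

    ci: float
    si: float
    tv: float

    def __post_init__(self) -> None:
        if not (0.0 < self.ci < 90.0):
            raise InconsistentAnglesError("ci must lie in (0, 90) degrees")
        if not (-90.0 < self.si < 90.0 and -90.0 < self.tv < 90.0):
            raise InconsistentAnglesError("si and tv must lie in (-90, 90) degrees")
        lhs = _tan_deg(self.tv)
        rhs = _tan_deg(self.si) * _tan_deg(self.ci)
        if abs(lhs - rhs) > 1e-9 * max(1.0, abs(lhs)):
            raise InconsistentAnglesError(
                f"angles violate tan(tv) = tan(si)*tan(ci): "
                f"tan(tv)={lhs!r}, tan(si)*tan(ci)={rhs!r}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ci, self.si, self.tv)


@dataclass(frozen=True)
class FemoralLandmarks:
    """3-D landmarks (mm) defining the mechanical femoral frame.

    ``head_center``/``knee_center`` span the mechanical femoral axis;
    the two posterior condyle points span the posterior condylar plane used
    as the distal rotational reference.
    """

    head_center: np.ndarray
    knee_center: np.ndarray
    medial_posterior_condyle: np.ndarray
    lateral_posterior_condyle: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "head_center",
            "knee_center",
            "medial_posterior_condyle",
            "lateral_posterior_condyle",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        if np.linalg.norm(self.head_center - self.knee_center) <= 1e-9:
            raise FrameConstructionError("head and knee centers coincide")
        if (
            np.linalg.norm(self.medial_posterior_condyle - self.lateral_posterior_condyle)
            <= 1e-9
        ):
            raise FrameConstructionError("condyle points coincide")


@dataclass(frozen=True)
class PlaneMisalignment:
    """Deviation of the coronal-sagittal viewing angle from 90 degrees.

    ``delta`` is in degrees; ``delta = 5`` means the two views meet at 85
    degrees.  Positive delta rotates the sagittal view so that apparent
    anteversion decreases.
    """

    delta: float

    def __post_init__(self) -> None:
        if not abs(self.delta) < 45.0:
            raise ValueError("|delta| must be < 45 degrees")


def angles_from_axis(axis: NeckAxis, frame: AnatomicalFrame | None = None) -> OrientationAngles:
    """Project a neck axis onto the three planes of ``frame`` and return
    the (CI, SI, TV) triple.

    Uses ``atan2`` on the vector components (robust near CI = 90): with
    frame components ``(x, y, z)``, ``CI = atan2(z, x)``,
    ``SI = atan2(y, z)``, ``TV = atan2(y, x)``.  ``frame=None`` means the
    scanner frame (axis components already in frame coordinates).

    Raises :class:`DegenerateInputError` when the axis is (anti)parallel to
    a projection plane's normal, or when CI falls on/outside the open
    (0, 90) range (e.g. a perfectly horizontal axis).
    """
    if frame is None:
        x, y, z = axis.x, axis.y, axis.z
    else:
        x, y, z = frame.express(axis.as_array())
    tol = np.sin(np.radians(DEGENERACY_TOL_DEG))
    for plane, norm in (
        ("coronal", np.hypot(x, z)),
        ("sagittal", np.hypot(y, z)),
        ("transverse", np.hypot(x, y)),
    ):
        if norm <= tol:
            raise DegenerateInputError(
                f"axis is (anti)parallel to the {plane}-plane normal: "
                f"{plane} projection is degenerate"
            )
    if not x > 0.0:
        raise DegenerateInputError(
            "axis must point medially (positive x) in the measurement frame"
        )
    ci = float(np.degrees(np.arctan2(z, x)))
    si = float(np.degrees(np.arctan2(y, z)))
    tv = float(np.degrees(np.arctan2(y, x)))
    if not (DEGENERACY_TOL_DEG < ci < 90.0 - DEGENERACY_TOL_DEG):
        raise DegenerateInputError(
            f"coronal inclination {ci:.4f} deg is outside the open (0, 90) "
            "working range (axis on/near the horizontal or vertical)"
        )
    return OrientationAngles(ci=ci, si=si, tv=tv)


def axis_from_angles(ci: float, tv: float) -> NeckAxis:
    """Unit neck axis with the given coronal inclination and transverse
    version (degrees): the normalization of ``(1, tan tv, tan ci)``.

    Inverse of :func:`angles_from_axis` up to the unit-norm, medial-pointing
    representative.
    """
    ci_a = np.asarray(ci, dtype=float)
    tv_a = np.asarray(tv, dtype=float)
    _check_open("ci", ci_a, DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    _check_open("tv", tv_a, -90.0 + DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    return NeckAxis.from_vector([1.0, float(_tan_deg(tv_a)), float(_tan_deg(ci_a))])


def mechanical_frame(landmarks: FemoralLandmarks) -> AnatomicalFrame:
    """Mechanical femoral frame from bony landmarks.

    ``e_z`` is the mechanical femoral axis (knee center to femoral head
    center); ``e_x`` is the posterior condylar direction (lateral to medial
    condyle) orthogonalized against ``e_z``; ``e_y = e_z x e_x`` completes a
    right-handed triad.  Origin is the femoral head center.
    """
    e_z = landmarks.head_center - landmarks.knee_center
    e_z = e_z / np.linalg.norm(e_z)
    raw_x = landmarks.medial_posterior_condyle - landmarks.lateral_posterior_condyle
    raw_x = raw_x - np.dot(raw_x, e_z) * e_z
    n = np.linalg.norm(raw_x)
    if n <= 1e-9:
        raise FrameConstructionError(
            "condylar direction is parallel to the mechanical axis"
        )
    e_x = raw_x / n
    e_y = np.cross(e_z, e_x)
    return AnatomicalFrame(origin=landmarks.head_center, e_x=e_x, e_y=e_y, e_z=e_z)


def apparent_tv(tv, delta):
    """Apparent transverse version under non-orthogonal viewing.

    Closed form ``tan tv' = tan(tv) * cos(delta) - sin(delta)`` for a
    sagittal view rotated by ``delta`` degrees about the vertical axis
    (positive delta reduces apparent anteversion).  Vectorized in ``tv``.
    """
    tv_a = np.asarray(tv, dtype=float)
    _check_open("tv", tv_a, -90.0 + DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    if not abs(float(delta)) < 45.0:
        raise ValueError("|delta| must be < 45 degrees")
    d = np.radians(float(delta))
    out = _atan_deg(_tan_deg(tv_a) * np.cos(d) - np.sin(d))
    return _scalar_like(out, tv)


def apparent_si(ci, si, delta):
    """Apparent sagittal inclination on a sagittal plane rotated by
    ``delta`` degrees about the vertical axis.

    ``tan si' = tan(si) * cos(delta) - sin(delta) / tan(ci)``; combined with
    the unrotated CI through the product identity this reproduces
    :func:`apparent_tv`.  Vectorized.
    """
    ci_a = np.asarray(ci, dtype=float)
    si_a = np.asarray(si, dtype=float)
    _check_open("ci", ci_a, DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    _check_open("si", si_a, -90.0 + DEGENERACY_TOL_DEG, 90.0 - DEGENERACY_TOL_DEG)
    if not abs(float(delta)) < 45.0:
        raise ValueError("|delta| must be < 45 degrees")
    d = np.radians(float(delta))
    out = _atan_deg(_tan_deg(si_a) * np.cos(d) - np.sin(d) / _tan_deg(ci_a))
    return _scalar_like(out, ci, si)


def apparent_angles_nonorthogonal(
    axis: NeckAxis,
    frame: AnatomicalFrame | None = None,
    mis: PlaneMisalignment = PlaneMisalignment(0.0),
) -> OrientationAngles:
    """Angles recovered when the sagittal view is misaligned by
    ``mis.delta`` degrees.

    CI is measured on the (unrotated) coronal view; SI is measured on a
    sagittal plane rotated by ``delta`` about the vertical axis; TV is then
    *calculated* from this mismatched (CI, SI') pair via
    :func:`tv_from_ci_si` — the situation of applying the reconstruction to
    non-orthogonal radiographs.  ``delta = 0`` reduces to
    :func:`angles_from_axis`.
    """
    base = angles_from_axis(axis, frame)
    if mis.delta == 0.0:
        return base
    if frame is None:
        x, y, z = axis.x, axis.y, axis.z
    else:
        x, y, z = frame.express(axis.as_array())
    d = np.radians(mis.delta)
    # rotating the viewing plane by +delta about e_z == rotating the axis by
    # -delta before the standard sagittal projection
    y_rot = y * np.cos(d) - x * np.sin(d)
    si_app = float(np.degrees(np.arctan2(y_rot, z)))
    tv_app = tv_from_ci_si(base.ci, si_app)
    return OrientationAngles(ci=base.ci, si=si_app, tv=tv_app)
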