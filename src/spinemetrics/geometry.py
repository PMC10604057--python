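"""Signed sagittal-parameter geometry from an 11-landmark set.

Twelve angular parameters of spinopelvic sagittal alignment are computed
from eleven named anatomical points on a lateral whole-spine radiograph:
the centers of both femoral heads, the center of the sacrum, and the
anterior/posterior endpoints of the S1, L1 and T1 superior endplates and
the C2 inferior endplate.

Three pelvic parameters (PI, PT, SS) and three incidence angles of the
inflection points (L1I, T1I, C2I) are measured directly; the six test
parameters (LL, TK, C2-7L, L1S, T1S, C2S) are obtained both directly from
endplate orientations and by the incidence-angle difference equations

    LL    = L1I - PI        L1S = L1I - PT
    TK    = T1I - L1I       T1S = T1I - PT
    C2-7L = T1I - C2I       C2S = C2I - PT

which hold exactly (not approximately) under the sign conventions below.

Sign conventions
----------------
Coordinates are image pixels: origin top-left, x rightward, y downward.
Patient orientation is an explicit :class:`FrameConvention` (anterior is
``+x`` or ``-x``; "up" is always ``-y``).  Internally every vector is
mapped to an anatomical frame with X = anterior, Y = up.  In that frame:

* a slope (SS, L1S, T1S, C2S) is positive when the endplate's anterior
  end is inferior to its posterior end;
* PT is positive when the S1 endplate midpoint lies posterior to the
  femoral-head midpoint;
* an incidence angle (PI, L1I, T1I, C2I) is positive when the endplate
  perpendicular lies anterior to the pelvic-tilt line;
* lordosis is negative and kyphosis positive.

With these choices ``PI = PT + SS`` and ``XI = XS + PT`` for each
inflection point X are exact signed identities for every landmark set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Dict, Iterator, Tuple

import numpy as np

__all__ = [
    "Point2D",
    "FrameConvention",
    "LandmarkSet",
    "PelvicParameters",
    "IncidenceAngles",
    "TestParameters",
    "SagittalReport",
    "DegenerateGeometryError",
    "LANDMARK_NAMES",
    "TEST_PARAMETER_NAMES",
    "signed_angle_between",
    "pt_line",
    "compute_pelvic_parameters",
    "compute_slopes",
    "compute_incidence_angles",
    "compute_direct_parameters",
    "derive_test_parameters",
    "full_report",
]

#: Canonical names of the 11 landmarks, in schema order.
LANDMARK_NAMES: Tuple[str, ...] = (
    "femoral_head_1",
    "femoral_head_2",
    "sacrum_center",
    "s1_sup_ant",
    "s1_sup_post",
    "l1_sup_ant",
    "l1_sup_post",
    "t1_sup_ant",
    "t1_sup_post",
    "c2_inf_ant",
    "c2_inf_post",
)

#: The six test parameters, in reporting order.
TEST_PARAMETER_NAMES: Tuple[str, ...] = ("LL", "TK", "C2_7L", "L1S", "T1S", "C2S")


class DegenerateGeometryError(ValueError):
    """Raised when landmark geometry degenerates (coincident points, zero vectors)."""


@dataclass(frozen=True)
class Point2D:
    """A point in image pixel coordinates (origin top-left, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class FrameConvention:
    """Patient orientation of the image frame.

    ``anterior_direction`` states which image x direction the patient
    faces; it is never inferred from pixel content.  "Up" is the -y image
    axis in either case.
    """

    anterior_direction: str = "+x"

    def __post_init__(self) -> None:
        if self.anterior_direction not in ("+x", "-x"):
            raise ValueError(
                f"anterior_direction must be '+x' or '-x', got {self.anterior_direction!r}"
            )

    @property
    def anterior_sign(self) -> float:
        return 1.0 if self.anterior_direction == "+x" else -1.0

    def to_anatomical(self, v: np.ndarray) -> np.ndarray:
        """Map an image-frame vector to the (anterior, up) frame."""
        v = np.asarray(v, dtype=float)
        return np.array([self.anterior_sign * v[0], -v[1]])

    def to_image(self, v: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_anatomical` (the map is an involution per axis)."""
        v = np.asarray(v, dtype=float)
        return np.array([self.anterior_sign * v[0], -v[1]])


@dataclass(frozen=True)
class LandmarkSet:
    """The 11 named anatomical points of one radiograph.

    Femoral heads may coincide (a perfect lateral projection); endplate
    endpoints must be distinct, and the femoral midpoint must differ from
    the S1 superior-endplate midpoint.
    """

    femoral_head_1: Point2D
    femoral_head_2: Point2D
    sacrum_center: Point2D
    s1_sup_ant: Point2D
    s1_sup_post: Point2D
    l1_sup_ant: Point2D
    l1_sup_post: Point2D
    t1_sup_ant: Point2D
    t1_sup_post: Point2D
    c2_inf_ant: Point2D
    c2_inf_post: Point2D

    def __post_init__(self) -> None:
        for ant, post, level in (
            (self.s1_sup_ant, self.s1_sup_post, "S1"),
            (self.l1_sup_ant, self.l1_sup_post, "L1"),
            (self.t1_sup_ant, self.t1_sup_post, "T1"),
            (self.c2_inf_ant, self.c2_inf_post, "C2"),
        ):
            if ant.x == post.x and ant.y == post.y:
                raise DegenerateGeometryError(
                    f"{level} endplate endpoints coincide at ({ant.x}, {ant.y})"
                )
        fm = self.femoral_midpoint()
        sm = self.s1_midpoint()
        if fm[0] == sm[0] and fm[1] == sm[1]:
            raise DegenerateGeometryError(
                "femoral-head midpoint coincides with the S1 endplate midpoint"
            )

    # -- accessors -----------------------------------------------------------

    def __iter__(self) -> Iterator[Tuple[str, Point2D]]:
        for name in LANDMARK_NAMES:
            yield name, getattr(self, name)

    def __getitem__(self, name: str) -> Point2D:
        if name not in LANDMARK_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def femoral_midpoint(self) -> np.ndarray:
        return 0.5 * (self.femoral_head_1.as_array() + self.femoral_head_2.as_array())

    def s1_midpoint(self) -> np.ndarray:
        return 0.5 * (self.s1_sup_ant.as_array() + self.s1_sup_post.as_array())

    def endplate_vector(self, level: str) -> np.ndarray:
        """Posterior-to-anterior endplate vector (image frame) for S1/L1/T1/C2."""
        key = level.lower()
        suffix = "inf" if key == "c2" else "sup"
        ant = getattr(self, f"{key}_{suffix}_ant").as_array()
        post = getattr(self, f"{key}_{suffix}_post").as_array()
        return ant - post

    def as_dict(self) -> Dict[str, Tuple[float, float]]:
        return {name: (pt.x, pt.y) for name, pt in self}

    @classmethod
    def from_dict(cls, coords: Dict[str, Tuple[float, float]]) -> "LandmarkSet":
        missing = [n for n in LANDMARK_NAMES if n not in coords]
        if missing:
            raise ValueError(f"missing landmarks: {', '.join(missing)}")
        extra = [n for n in coords if n not in LANDMARK_NAMES]
        if extra:
            raise ValueError(f"unknown landmarks: {', '.join(extra)}")
        return cls(**{n: Point2D(*coords[n]) for n in LANDMARK_NAMES})

    def as_array(self) -> np.ndarray:
        """(11, 2) array of coordinates in schema order."""
        return np.array([[pt.x, pt.y] for _, pt in self])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (11, 2):
            raise ValueError(f"expected shape (11, 2), got {arr.shape}")
        return cls(**{n: Point2D(*xy) for n, xy in zip(LANDMARK_NAMES, arr)})

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn: (n,2) array -> (n,2) array`` to all coordinates."""
        return LandmarkSet.from_array(np.asarray(fn(self.as_array()), dtype=float))


@dataclass(frozen=True)
class PelvicParameters:
    """Pelvic incidence, pelvic tilt and sacral slope, degrees, signed."""

    PI: float
    PT: float
    SS: float


@dataclass(frozen=True)
class IncidenceAngles:
    """Incidence angles of the three inflection points (L1, T1, C2), degrees."""

    L1I: float
    T1I: float
    C2I: float


@dataclass(frozen=True)
class TestParameters:
    """The six derived-or-direct test parameters, degrees, signed."""

    LL: float
    TK: float
    C2_7L: float
    L1S: float
    T1S: float
    C2S: float

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SagittalReport:
    """Full measurement of one landmark set.

    ``direct`` holds the six test parameters measured from endplate
    orientations; ``derived`` the same six obtained from the incidence
    equations; ``discrepancy`` their absolute differences, which vanish
    analytically and differ from zero only by floating-point rounding.
    """

    pelvic: PelvicParameters
    incidences: IncidenceAngles
    direct: TestParameters
    derived: TestParameters
    discrepancy: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, object]:
        return {
            "pelvic": {"PI": self.pelvic.PI, "PT": self.pelvic.PT, "SS": self.pelvic.SS},
            "incidences": {
                "L1I": self.incidences.L1I,
                "T1I": self.incidences.T1I,
                "C2I": self.incidences.C2I,
            },
            "direct": self.direct.as_dict(),
            "derived": self.derived.as_dict(),
            "discrepancy": dict(self.discrepancy),
        }

    @classmethod
    def from_dict(cls, d: Dict[str, object]) -> "SagittalReport":
        return cls(
            pelvic=PelvicParameters(**d["pelvic"]),
            incidences=IncidenceAngles(**d["incidences"]),
            direct=TestParameters(**d["direct"]),
            derived=TestParameters(**d["derived"]),
            discrepancy=dict(d["discrepancy"]),
        )


# -- angle primitives ---------------------------------------------------------


def _wrap(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    wrapped = math.fmod(deg + 180.0, 360.0)
    if wrapped <= 0.0:
        wrapped += 360.0
    return wrapped - 180.0


def _check_nonzero(v: np.ndarray, what: str) -> None:
    if v[0] == 0.0 and v[1] == 0.0:
        raise DegenerateGeometryError(f"zero-length vector: {what}")


def signed_angle_between(v1, v2, frame: FrameConvention) -> float:
    """Directed angle from ``v1`` to ``v2`` in degrees, in (-180, 180].

    The magnitude is the arccosine of the normalized dot product; the sign
    comes from the 2-D cross product evaluated in the anatomical
    (anterior, up) frame defined by ``frame``: positive rotations carry
    "up" toward "posterior" (the sense in which pelvic tilt is positive).
    """
    a1 = frame.to_anatomical(np.asarray(v1, dtype=float))
    a2 = frame.to_anatomical(np.asarray(v2, dtype=float))
    _check_nonzero(a1, "first vector")
    _check_nonzero(a2, "second vector")
    cross = a1[0] * a2[1] - a1[1] * a2[0]
    dot = a1[0] * a2[0] + a1[1] * a2[1]
    return _wrap(math.degrees(math.atan2(cross, dot)))


def pt_line(landmarks: LandmarkSet) -> np.ndarray:
    """Pelvic-tilt line: femoral-head midpoint to S1 endplate midpoint (image frame)."""
    v = landmarks.s1_midpoint() - landmarks.femoral_midpoint()
    if v[0] == 0.0 and v[1] == 0.0:
        raise DegenerateGeometryError(
            "pelvic-tilt line is degenerate: femoral midpoint equals S1 midpoint"
        )
    return v


def _phi(v: np.ndarray) -> float:
    """Counterclockwise angle of an anatomical-frame vector, degrees."""
    return math.degrees(math.atan2(v[1], v[0]))


def _rot90_toward_up(v: np.ndarray) -> np.ndarray:
    """Endplate perpendicular: posterior-to-anterior vector rotated 90 deg toward up.

    Operates in the anatomical frame, where the rotation is counterclockwise.
    """
    return np.array([-v[1], v[0]])


def _slope(landmarks: LandmarkSet, level: str, frame: FrameConvention) -> float:
    """Signed slope of an endplate vs the horizontal; anterior-end-down positive."""
    e = frame.to_anatomical(landmarks.endplate_vector(level))
    _check_nonzero(e, f"{level} endplate")
    return _wrap(-_phi(e))


def _incidence(landmarks: LandmarkSet, level: str, frame: FrameConvention) -> float:
    """Signed angle from the endplate perpendicular to the pelvic-tilt line."""
    e = frame.to_anatomical(landmarks.endplate_vector(level))
    _check_nonzero(e, f"{level} endplate")
    p = frame.to_anatomical(pt_line(landmarks))
    n = _rot90_toward_up(e)
    cross = n[0] * p[1] - n[1] * p[0]
    dot = n[0] * p[0] + n[1] * p[1]
    return _wrap(math.degrees(math.atan2(cross, dot)))


# -- parameter computations ---------------------------------------------------


def compute_pelvic_parameters(
    landmarks: LandmarkSet, frame: FrameConvention = FrameConvention()
) -> PelvicParameters:
    """Measure PI, PT and SS from the landmark set.

    PI is the angle between the pelvic-tilt line and the S1 endplate
    perpendicular; PT the angle between the vertical and the pelvic-tilt
    line (posterior tilt positive); SS the angle between the S1 endplate
    and the horizontal.  The signed identity ``PI = PT + SS`` holds to
    floating-point precision.
    """
    p = frame.to_anatomical(pt_line(landmarks))
    pt = _wrap(_phi(p) - 90.0)
    ss = _slope(landmarks, "s1", frame)
    pi = _incidence(landmarks, "s1", frame)
    return PelvicParameters(PI=pi, PT=pt, SS=ss)


def compute_slopes(
    landmarks: LandmarkSet, frame: FrameConvention = FrameConvention()
) -> Dict[str, float]:
    """Signed slopes of the S1, L1, T1 and C2 endplates vs the horizontal."""
    return {
        "SS": _slope(landmarks, "s1", frame),
        "L1S": _slope(landmarks, "l1", frame),
        "T1S": _slope(landmarks, "t1", frame),
        "C2S": _slope(landmarks, "c2", frame),
    }


def compute_incidence_angles(
    landmarks: LandmarkSet, frame: FrameConvention = FrameConvention()
) -> IncidenceAngles:
    """Measure the incidence angles of the inflection points L1, T1 and C2.

    Each is the signed angle between the pelvic-tilt line and the
    perpendicular of the named endplate (L1/T1 superior, C2 inferior),
    positive when the perpendicular lies anterior to the line.  For each
    level X, ``XI = XS + PT`` holds to floating-point precision.
    """
    return IncidenceAngles(
        L1I=_incidence(landmarks, "l1", frame),
        T1I=_incidence(landmarks, "t1", frame),
        C2I=_incidence(landmarks, "c2", frame),
    )


def compute_direct_parameters(
    landmarks: LandmarkSet, frame: FrameConvention = FrameConvention()
) -> TestParameters:
    """Measure the six test parameters directly from endplate orientations.

    Regional angles are signed Cobb angles between the named endplates
    (LL: L1 vs S1 superior; TK: T1 vs L1 superior; C2-7L: T1 superior vs
    C2 inferior); slopes are signed angles vs the horizontal.  Lordosis is
    negative, kyphosis positive.
    """

    def cobb(upper: str, lower: str) -> float:
        eu = frame.to_anatomical(landmarks.endplate_vector(upper))
        el = frame.to_anatomical(landmarks.endplate_vector(lower))
        _check_nonzero(eu, f"{upper} endplate")
        _check_nonzero(el, f"{lower} endplate")
        # directed angle in the slope sense: slope(upper) - slope(lower)
        cross = eu[0] * el[1] - eu[1] * el[0]
        dot = eu[0] * el[0] + eu[1] * el[1]
        return _wrap(math.degrees(math.atan2(cross, dot)))

    slopes = compute_slopes(landmarks, frame)
    return TestParameters(
        LL=cobb("l1", "s1"),
        TK=cobb("t1", "l1"),
        C2_7L=cobb("t1", "c2"),
        L1S=slopes["L1S"],
        T1S=slopes["T1S"],
        C2S=slopes["C2S"],
    )


def derive_test_parameters(
    pelvic: PelvicParameters, incidences: IncidenceAngles
) -> TestParameters:
    """Derive the six test parameters from pelvic parameters and incidences.

    Pure arithmetic on the incidence-angle differences::

        LL    = L1I - PI        L1S = L1I - PT
        TK    = T1I - L1I       T1S = T1I - PT
        C2-7L = T1I - C2I       C2S = C2I - PT
    """
    vals = [pelvic.PI, pelvic.PT, incidences.L1I, incidences.T1I, incidences.C2I]
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite input parameter")
    return TestParameters(
        LL=_wrap(incidences.L1I - pelvic.PI),
        TK=_wrap(incidences.T1I - incidences.L1I),
        C2_7L=_wrap(incidences.T1I - incidences.C2I),
        L1S=_wrap(incidences.L1I - pelvic.PT),
        T1S=_wrap(incidences.T1I - pelvic.PT),
        C2S=_wrap(incidences.C2I - pelvic.PT),
    )


def full_report(
    landmarks: LandmarkSet, frame: FrameConvention = FrameConvention()
) -> SagittalReport:
    """Measure all 12 parameters, both directly and via the incidence equations."""
    pelvic = compute_pelvic_parameters(landmarks, frame)
    incidences = compute_incidence_angles(landmarks, frame)
    direct = compute_direct_parameters(landmarks, frame)
    derived = derive_test_parameters(pelvic, incidences)
    discrepancy = {
        name: abs(getattr(direct, name) - getattr(derived, name))
        for name in TEST_PARAMETER_NAMES
    }
    return SagittalReport(
        pelvic=pelvic,
        incidences=incidences,
        direct=direct,
        derived=derived,
        discrepancy=discrepancy,
    )
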