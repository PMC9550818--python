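"""Landmark data model and radiographic parameter measurements.

Coordinate frame
----------------
All landmarks live in millimetres on a standing long-cassette film.  On the
coronal (postero-anterior) film ``x`` is positive toward the patient's left
and ``y`` is positive cranial.  On the sagittal film ``x`` is positive
anterior, ``y`` positive cranial.  Display conversions (cm for trunk-shift
and apical translation) happen inside the measurement functions that report
in cm; everything else stays in mm and degrees.

Sign conventions
----------------
Positive clavicular angle, T1 tilt and radiographic shoulder height (RSH)
all mean "left side elevated".  Cobb angles are unsigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from shapely.geometry import Polygon

from . import levels as lv
from .errors import DegenerateGeometryError, LevelError, SchemaError

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Point2D:
    """A planar landmark in millimetres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"non-finite coordinates ({self.x}, {self.y})")

    def translated(self, dx: float, dy: float) -> "Point2D":
        return Point2D(self.x + dx, self.y + dy)


@dataclass(frozen=True, slots=True)
class VertebraCoronal:
    """One vertebra on the PA film.

    ``body_corners`` are ordered (upper-left, upper-right, lower-right,
    lower-left), "left" meaning the patient's left (+x).
    """

    level: str
    body_corners: tuple[Point2D, Point2D, Point2D, Point2D]
    spinous_center: Point2D

    def __post_init__(self) -> None:
        lv.index(self.level)
        if len(self.body_corners) != 4:
            raise SchemaError(f"{self.level}: body must have 4 corners")
        if not self.polygon.is_valid:
            raise SchemaError(f"{self.level}: body corners self-intersect")
        ul, ur, lr, ll = self.body_corners
        if (ul.y + ur.y) / 2 <= (ll.y + lr.y) / 2:
            raise SchemaError(f"{self.level}: upper corners below lower corners")

    @property
    def polygon(self) -> Polygon:
        return Polygon([(p.x, p.y) for p in self.body_corners])

    @property
    def centroid(self) -> Point2D:
        xs = [p.x for p in self.body_corners]
        ys = [p.y for p in self.body_corners]
        return Point2D(sum(xs) / 4.0, sum(ys) / 4.0)

    @property
    def upper_endplate(self) -> tuple[Point2D, Point2D]:
        return self.body_corners[0], self.body_corners[1]

    @property
    def lower_endplate(self) -> tuple[Point2D, Point2D]:
        return self.body_corners[3], self.body_corners[2]


@dataclass(frozen=True)
class SpineCoronal:
    """All coronal landmarks of one PA film: C7 through L5 plus shoulder
    girdle points and the S1 upper-endplate centre (CSVL anchor)."""

    vertebrae: tuple[VertebraCoronal, ...]
    clavicle_left_high: Point2D
    clavicle_right_high: Point2D
    shoulder_left: Point2D
    shoulder_right: Point2D
    s1_center: Point2D
    _by_level: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        want = lv.CORONAL_LEVELS
        got = tuple(v.level for v in self.vertebrae)
        if got != want:
            raise SchemaError(
                f"coronal film must carry levels {want[0]}..{want[-1]} in order; got {got}"
            )
        ys = [v.centroid.y for v in self.vertebrae]
        if any(lower >= upper for lower, upper in zip(ys[1:], ys[:-1])):
            raise SchemaError("vertebral centroids must strictly decrease in y from C7 caudally")
        object.__setattr__(self, "_by_level", {v.level: v for v in self.vertebrae})

    def vertebra(self, level: str) -> VertebraCoronal:
        try:
            return self._by_level[level]
        except KeyError:
            raise LevelError(f"level {level} not on coronal film") from None


@dataclass(frozen=True)
class SpineSagittal:
    """Sagittal endplate landmarks, T1 through S1.

    Each level carries an ``upper_endplate`` and ``lower_endplate`` pair of
    points (posterior/anterior ends of the endplate line).
    """

    endplates: dict  # level -> {"upper": (Point2D, Point2D), "lower": (...)}

    def __post_init__(self) -> None:
        for level in lv.SAGITTAL_LEVELS:
            if level not in self.endplates:
                raise SchemaError(f"sagittal film missing level {level}")
            for side in ("upper", "lower"):
                pair = self.endplates[level][side]
                if math.hypot(pair[0].x - pair[1].x, pair[0].y - pair[1].y) <= 0:
                    raise SchemaError(f"{level} {side} endplate is degenerate")

    def endplate(self, level: str, side: str) -> tuple[Point2D, Point2D]:
        if level not in self.endplates:
            raise LevelError(f"level {level} not on sagittal film")
        return self.endplates[level][side]


@dataclass(frozen=True, slots=True)
class RadiographicParams:
    """One film's worth of the study's radiographic parameters."""

    pt_cobb: float  # degrees, >= 0
    mt_cobb: float  # degrees, >= 0
    c7pl_csvl: float  # cm, absolute
    ca: float  # degrees, signed (+ = left clavicle higher)
    t1_tilt: float  # degrees, signed (+ = left end of T1 upper endplate higher)
    rsh: float  # mm, signed (left minus right shoulder height)
    mt_avt: float  # cm, >= 0
    tk_t5_t12: float | None = None  # degrees
    ll_t12_s1: float | None = None  # degrees

    def __post_init__(self) -> None:
        for name in ("pt_cobb", "mt_cobb", "c7pl_csvl", "mt_avt"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise SchemaError(f"{name} must be finite and non-negative, got {v}")
        for name in ("ca", "t1_tilt", "rsh"):
            if not math.isfinite(getattr(self, name)):
                raise SchemaError(f"{name} must be finite")


# Default end-vertebra search windows for the two curves of a double thoracic
# (Lenke 2) pattern.  The proximal thoracic (PT) curve is sought between C7
# and T6, the main thoracic (MT) curve between T4 and L2.
DEFAULT_WINDOWS: dict[str, tuple[str, str]] = {"PT": ("C7", "T6"), "MT": ("T4", "L2")}


# --------------------------------------------------------------------------
# Primitive angle measurements
# --------------------------------------------------------------------------


def endplate_angle(p1: Point2D, p2: Point2D) -> float:
    """Signed inclination of the line p1-p2 from horizontal, in degrees.

    Positive when the patient-left end (larger x) is higher; result lies in
    (-90, 90], a vertical line mapping to 90.
    """
    dx, dy = p2.x - p1.x, p2.y - p1.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("endplate endpoints coincide")
    if dx < 0:
        dx, dy = -dx, -dy
    if dx == 0.0:
        return 90.0
    return math.degrees(math.atan2(dy, dx))


def _line_angle_between(a: tuple[Point2D, Point2D], b: tuple[Point2D, Point2D]) -> float:
    """Unsigned angle in [0, 90] between two undirected lines."""
    ux, uy = a[1].x - a[0].x, a[1].y - a[0].y
    vx, vy = b[1].x - b[0].x, b[1].y - b[0].y
    nu = math.hypot(ux, uy)
    nv = math.hypot(vx, vy)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("degenerate endplate line")
    c = abs(ux * vx + uy * vy) / (nu * nv)
    return math.degrees(math.acos(min(1.0, c)))


def cobb_angle(spine: SpineCoronal | SpineSagittal, upper_level: str, lower_level: str) -> float:
    """Cobb angle between the upper endplate of *upper_level* and the lower
    endplate of *lower_level*, in degrees (>= 0).

    Invariant under rigid rotation and translation of the landmark set.
    """
    if not lv.is_cranial(upper_level, lower_level):
        raise LevelError(f"{upper_level} must be cranial to {lower_level}")
    if isinstance(spine, SpineCoronal):
        upper = spine.vertebra(upper_level).upper_endplate
        lower = spine.vertebra(lower_level).lower_endplate
    else:
        upper = spine.endplate(upper_level, "upper")
        lower = spine.endplate(lower_level, "lower")
    return _line_angle_between(upper, lower)


def auto_end_vertebrae(
    spine: SpineCoronal,
    region: str,
    windows: dict[str, tuple[str, str]] | None = None,
) -> tuple[str, str]:
    """End vertebrae of a curve: the pair of levels inside the region window
    whose endplates subtend the largest Cobb angle.

    Ties break toward the more cranial pair (upper level first, then lower).
    A straight spine therefore returns the most cranial window pair at 0 deg.
    """
    windows = windows or DEFAULT_WINDOWS
    if region not in windows:
        raise LevelError(f"unknown curve region {region!r}")
    candidates = lv.span(*windows[region])
    best: tuple[str, str] | None = None
    best_angle = -1.0
    for i, upper in enumerate(candidates):
        for lower in candidates[i + 1 :]:
            ang = cobb_angle(spine, upper, lower)
            if ang > best_angle + 1e-12:
                best_angle = ang
                best = (upper, lower)
    assert best is not None
    return best


# --------------------------------------------------------------------------
# Coronal balance and shoulder parameters
# --------------------------------------------------------------------------


def c7pl_csvl_distance(spine: SpineCoronal) -> float:
    """Horizontal offset between the C7 plumb line (vertical through the C7
    body centroid) and the CSVL (vertical through the S1 centre), in cm."""
    return abs(spine.vertebra("C7").centroid.x - spine.s1_center.x) / 10.0


def clavicular_angle(spine: SpineCoronal) -> float:
    """Inclination of the line through the two clavicle highest points
    (degrees; positive = left clavicle higher)."""
    return endplate_angle(spine.clavicle_right_high, spine.clavicle_left_high)


def t1_tilt(spine: SpineCoronal) -> float:
    """Inclination of the T1 upper endplate (degrees; positive = left up)."""
    return endplate_angle(*spine.vertebra("T1").upper_endplate)


def rsh(spine: SpineCoronal) -> float:
    """Radiographic shoulder height: y(left shoulder) - y(right shoulder), mm.

    The imbalance classification uses |RSH|; the sign encodes which shoulder
    is elevated (positive = left)."""
    return spine.shoulder_left.y - spine.shoulder_right.y


def mt_apex(spine: SpineCoronal, search: tuple[str, str] = ("T4", "T12")) -> str:
    """Main thoracic apical vertebra: body centroid horizontally farthest
    from the C7 plumb line within the thoracic search window."""
    c7x = spine.vertebra("C7").centroid.x
    best, best_d = None, -1.0
    for level in lv.span(*search):
        d = abs(spine.vertebra(level).centroid.x - c7x)
        if d > best_d + 1e-12:
            best, best_d = level, d
    assert best is not None
    return best


def mt_avt(spine: SpineCoronal, apex_level: str | None = None) -> float:
    """Main thoracic apical vertebral translation: horizontal distance of
    the apical body centroid from the C7 plumb line, in cm."""
    apex = apex_level or mt_apex(spine)
    c7x = spine.vertebra("C7").centroid.x
    return abs(spine.vertebra(apex).centroid.x - c7x) / 10.0


# --------------------------------------------------------------------------
# Junctional complications
# --------------------------------------------------------------------------


def proximal_junctional_angle(sag: SpineSagittal, uiv: str) -> float | None:
    """Sagittal Cobb between the lower endplate of the UIV and the upper
    endplate of the vertebra two levels cranial; None when the supradjacent
    levels fall off the sagittal film (UIV at T1/T2)."""
    try:
        upper_level = lv.shift(uiv, -2)
    except LevelError:
        return None
    if upper_level not in sag.endplates:
        return None
    upper = sag.endplate(upper_level, "upper")
    lower = sag.endplate(uiv, "lower")
    return _line_angle_between(upper, lower)


def pjk_criteria(pre_angle: float, post_angle: float) -> bool:
    """The PJK rule on measured junctional angles: postoperative angle
    strictly greater than 10 degrees AND at least 10 degrees greater than
    the preoperative angle."""
    return post_angle > 10.0 and (post_angle - pre_angle) >= 10.0


def pjk_flag(sag_pre: SpineSagittal, sag_post: SpineSagittal, uiv: str) -> bool | None:
    """Proximal junctional kyphosis between two sagittal films; None (not
    evaluable) when the supradjacent levels are missing."""
    post = proximal_junctional_angle(sag_post, uiv)
    pre = proximal_junctional_angle(sag_pre, uiv)
    if post is None or pre is None:
        return None
    return pjk_criteria(pre, post)


def disc_angle_below(spine: SpineCoronal, liv: str) -> float:
    """Coronal angulation of the disc immediately caudal to the LIV: angle
    between the LIV lower endplate and the next level's upper endplate."""
    below = lv.shift(liv, 1)
    if below == "S1":
        raise LevelError("no coronal landmarks caudal to L5")
    return _line_angle_between(
        spine.vertebra(liv).lower_endplate, spine.vertebra(below).upper_endplate
    )


def adding_on_criteria(d_mt_cobb: float, ev_distalized: bool, d_disc_angle: float) -> bool:
    """The distal adding-on rule: Cobb increase >= 5 degrees with end-
    vertebra distalization, or a >= 5 degree change in the disc angulation
    below the LIV."""
    return (d_mt_cobb >= 5.0 and ev_distalized) or abs(d_disc_angle) >= 5.0


def adding_on_flag(
    first_erect: SpineCoronal | None,
    final: SpineCoronal,
    liv: str,
    windows: dict[str, tuple[str, str]] | None = None,
) -> bool | None:
    """Distal adding-on between the first-erect and final films; None when
    the first-erect film is absent."""
    if first_erect is None:
        return None
    ev0 = auto_end_vertebrae(first_erect, "MT", windows)
    ev1 = auto_end_vertebrae(final, "MT", windows)
    d_cobb = cobb_angle(final, *ev1) - cobb_angle(first_erect, *ev0)
    distalized = lv.index(ev1[1]) > lv.index(ev0[1])
    d_disc = disc_angle_below(final, liv) - disc_angle_below(first_erect, liv)
    return adding_on_criteria(d_cobb, distalized, d_disc)


# --------------------------------------------------------------------------
# Convenience bundle
# --------------------------------------------------------------------------


def measure_params(
    coronal: SpineCoronal,
    sagittal: SpineSagittal | None = None,
    windows: dict[str, tuple[str, str]] | None = None,
) -> RadiographicParams:
    """Measure every coronal (and, when available, sagittal) parameter of
    one film pair."""
    pt_ends = auto_end_vertebrae(coronal, "PT", windows)
    mt_ends = auto_end_vertebrae(coronal, "MT", windows)
    tk = ll = None
    if sagittal is not None:
        tk = cobb_angle(sagittal, "T5", "T12")
        ll = cobb_angle(sagittal, "T12", "S1")
    return RadiographicParams(
        pt_cobb=cobb_angle(coronal, *pt_ends),
        mt_cobb=cobb_angle(coronal, *mt_ends),
        c7pl_csvl=c7pl_csvl_distance(coronal),
        ca=clavicular_angle(coronal),
        t1_tilt=t1_tilt(coronal),
        rsh=rsh(coronal),
        mt_avt=mt_avt(coronal),
        tk_t5_t12=tk,
        ll_t12_s1=ll,
    )
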