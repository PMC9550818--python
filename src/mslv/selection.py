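"""Upper-instrumented-vertebra (UIV) selection.

Implements the modified Shinshu line (MSL) rule: the MSL is the segment
joining the C7 spinous-process centre to the spinous-process centre of the
lowest instrumented vertebra (LIV) on the preoperative standing PA film.
The MSL vertebra (MSLV) — the vertebral body first touched proximally by
that segment — is the recommended UIV.  For severe proximal thoracic curves
the segment may leave the vertebral column entirely; the MSLV is then the
most proximal body still touching the line (clamped caudally to T2).

Also implemented here: the three comparator recommendation systems (Lenke,
Ilharreborde as modified by Bjerke, Trobisch), the LIV selection rules for
Lenke 2A/2B/2C, matched/proximal/distal classification of the actual UIV
against a recommendation, and the sensitivity of the MSLV to one-level LIV
shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

from shapely.geometry import LineString

from . import levels as lv
from .errors import ExclusionError, LevelError
from .geometry import Point2D, RadiographicParams, SpineCoronal

#: Default contact tolerance: a body "touches" the MSL when its outline comes
#: within this distance (mm) of the segment.  Radiograph landmark digitization
#: noise is sub-millimetre, so tangency within 0.1 mm counts as touch.
DEFAULT_CONTACT_TOL = 0.1

#: Valid LIV range for MSL construction (study LIVs span T11..L4).
_LIV_RANGE = ("T11", "L4")

#: The complement recommendation of the Lenke method (any UIV caudal to T2)
#: when the left shoulder is not elevated.  Configurable; the source rule only
#: states the T2 arm.
LENKE_COMPLEMENT: tuple[str, ...] = ("T3", "T4", "T5", "T6")


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class MSLSegment:
    """The modified Shinshu line: LIV spinous centre to C7 spinous centre."""

    start: Point2D  # LIV spinous-process centre (caudal end)
    end: Point2D  # C7 spinous-process centre (cranial end)
    liv: str

    def __post_init__(self) -> None:
        if self.start.y >= self.end.y:
            raise LevelError("MSL start (LIV) must be caudal to its end (C7)")


@dataclass(frozen=True, slots=True)
class MSLVResult:
    """Outcome of the MSLV determination on one film."""

    mslv: str
    deviated: bool
    contact_levels: tuple[str, ...]  # cranial -> caudal


@dataclass(frozen=True, slots=True)
class BendingAngles:
    """Side-bending Cobb angles used by the Ilharreborde system.

    ``alpha``: proximal thoracic Cobb bending toward its convex (left) side;
    ``beta``: main thoracic Cobb bending toward its convex (right) side.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise LevelError("bending Cobb angles must be non-negative")


@dataclass(frozen=True, slots=True)
class UIVRecommendation:
    """A method's recommended UIV level set, with its match classification
    against the actually instrumented UIV once classified."""

    method: str  # MSLV | Lenke | Ilharreborde | Trobisch
    recommended_levels: frozenset[str]
    match_class: str | None = None  # matched | proximal | distal | unmatched


# --------------------------------------------------------------------------
# MSL construction and contact
# --------------------------------------------------------------------------


def construct_msl(spine: SpineCoronal, liv: str) -> MSLSegment:
    """Build the MSL for the given LIV (must lie in T11..L4)."""
    i = lv.index(liv)
    if not lv.index(_LIV_RANGE[0]) <= i <= lv.index(_LIV_RANGE[1]):
        raise LevelError(f"LIV must lie in {_LIV_RANGE[0]}..{_LIV_RANGE[1]}, got {liv}")
    return MSLSegment(
        start=spine.vertebra(liv).spinous_center,
        end=spine.vertebra("C7").spinous_center,
        liv=liv,
    )


def body_contact_set(
    spine: SpineCoronal, seg: MSLSegment, tol: float = DEFAULT_CONTACT_TOL
) -> tuple[str, ...]:
    """Levels strictly between C7 and the LIV whose body quadrilateral lies
    within *tol* mm of the MSL (intersection or tangency), cranial to caudal.
    """
    if tol < 0:
        raise LevelError("contact tolerance must be non-negative")
    line = LineString([(seg.start.x, seg.start.y), (seg.end.x, seg.end.y)])
    out = []
    for level in lv.ORDER[1 : lv.index(seg.liv)]:
        if spine.vertebra(level).polygon.distance(line) <= tol:
            out.append(level)
    return tuple(out)


def _runs(contacts: tuple[str, ...]) -> list[tuple[str, ...]]:
    """Split an ordered contact set into maximal runs of consecutive levels."""
    runs: list[list[str]] = []
    for level in contacts:
        if runs and lv.index(level) == lv.index(runs[-1][-1]) + 1:
            runs[-1].append(level)
        else:
            runs.append([level])
    return [tuple(r) for r in runs]


def determine_mslv(
    spine: SpineCoronal, liv: str, tol: float = DEFAULT_CONTACT_TOL
) -> MSLVResult:
    """The MSL vertebra for the given film and LIV.

    The contact set is decomposed into maximal runs of consecutive levels.
    Walking cranially from the LIV, the run contiguous with the LIV is the
    column the line leaves as it ascends and is discarded; the body "first
    touched proximally" is the most caudal level of the next run.  When the
    line leaves the column entirely in the proximal thoracic region (no
    contact anywhere in T3..T8 and first proximal contact at T2 or above) the
    spine is flagged *deviated* and the MSLV is the most proximal touching
    body, clamped caudally so that it is never cranial to T2.  A straight
    spine, whose LIV-contiguous run extends all the way to T1, clamps to T2.
    """
    seg = construct_msl(spine, liv)
    contacts = body_contact_set(spine, seg, tol)
    runs = _runs(contacts)

    liv_adjacent = lv.shift(liv, -1)
    liv_run: tuple[str, ...] | None = None
    if runs and runs[-1][-1] == liv_adjacent:
        liv_run = runs.pop()

    if liv_run is not None and liv_run[0] == "T1":
        # Straight (colinear) spine: the line never leaves the column.
        return MSLVResult(mslv="T2", deviated=False, contact_levels=contacts)

    if not runs:
        # Nothing touched above the LIV run: severe deviation.
        return MSLVResult(mslv="T2", deviated=True, contact_levels=contacts)

    candidate = runs[-1][-1]  # most caudal level of the next run going up
    t3_t8 = set(lv.span("T3", "T8"))
    if lv.is_cranial(candidate, "T3") and not t3_t8.intersection(contacts):
        most_proximal = contacts[0]
        mslv = "T2" if lv.is_cranial(most_proximal, "T2") else most_proximal
        return MSLVResult(mslv=mslv, deviated=True, contact_levels=contacts)

    # Clamp into [T2, level cranial to LIV].
    if lv.is_cranial(candidate, "T2"):
        candidate = "T2"
    if not lv.is_cranial(candidate, liv):
        candidate = liv_adjacent
    return MSLVResult(mslv=candidate, deviated=False, contact_levels=contacts)


# --------------------------------------------------------------------------
# Comparator recommendation systems
# --------------------------------------------------------------------------


def recommend_lenke(
    params: RadiographicParams, complement: tuple[str, ...] = LENKE_COMPLEMENT
) -> UIVRecommendation:
    """Lenke rule: fusion to T2 when the left shoulder is elevated (signed
    RSH > 0); otherwise any UIV caudal to T2 (the configurable complement
    set).  RSH exactly 0 counts as not elevated."""
    if params.rsh > 0:
        rec = frozenset({"T2"})
    else:
        rec = frozenset(complement)
    return UIVRecommendation(method="Lenke", recommended_levels=rec)


#: Ilharreborde/Bjerke cell map.  Rows: alpha - beta/2 below vs above 15 deg
#: (15 exactly goes to the "below" row).  Columns: T1 tilt and RSH both to
#: the left / in opposite directions (any zero counts as opposite) / both to
#: the right.
_ILHARREBORDE_TABLE: dict[tuple[str, str], frozenset[str]] = {
    ("low", "left"): frozenset({"T4", "T5", "T6"}),
    ("low", "opposite"): frozenset({"T2", "T3"}),
    ("low", "right"): frozenset({"T1", "T2"}),
    ("high", "left"): frozenset({"T2", "T3"}),
    ("high", "opposite"): frozenset({"T1", "T2"}),
    ("high", "right"): frozenset({"T1", "T2"}),
}


def recommend_ilharreborde(
    bend: BendingAngles, t1_tilt: float, rsh: float
) -> UIVRecommendation:
    """Ilharreborde system (Bjerke modification): a 2x3 table on the bending
    flexibility index alpha - beta/2 and the joint direction of T1 tilt and
    RSH."""
    row = "low" if bend.alpha - bend.beta / 2.0 <= 15.0 else "high"
    if t1_tilt > 0 and rsh > 0:
        col = "left"
    elif t1_tilt < 0 and rsh < 0:
        col = "right"
    else:
        col = "opposite"
    return UIVRecommendation(
        method="Ilharreborde", recommended_levels=_ILHARREBORDE_TABLE[(row, col)]
    )


def recommend_trobisch() -> UIVRecommendation:
    """Trobisch rule: fusion to T2 for every double thoracic curve."""
    return UIVRecommendation(method="Trobisch", recommended_levels=frozenset({"T2"}))


# --------------------------------------------------------------------------
# Match classification
# --------------------------------------------------------------------------


def classify_match(
    actual_uiv: str,
    rec: UIVRecommendation,
    mslv: MSLVResult | None = None,
) -> UIVRecommendation:
    """Classify the actually instrumented UIV against a recommendation.

    For the MSLV method the classes are matched / proximal (UIV cranial to
    the MSLV) / distal; for the comparator methods, matched / unmatched by
    set membership.  A T1 recommendation (Ilharreborde's "T1 or T2" cell) is
    honoured by an actual T2, mirroring how such recommendations are scored
    in practice.  Patients with a UIV cranial to T2 are excluded by design.
    """
    if lv.is_cranial(actual_uiv, "T2"):
        raise ExclusionError(f"UIV {actual_uiv} is cranial to T2 (study exclusion)")
    if lv.index(actual_uiv) > lv.index("T6"):
        raise ExclusionError(f"UIV {actual_uiv} is caudal to T6")

    if rec.method == "MSLV":
        if mslv is None:
            raise LevelError("MSLV classification requires an MSLVResult")
        ai, mi = lv.index(actual_uiv), lv.index(mslv.mslv)
        cls = "matched" if ai == mi else ("proximal" if ai < mi else "distal")
    else:
        matched = actual_uiv in rec.recommended_levels
        if rec.method == "Ilharreborde" and "T1" in rec.recommended_levels:
            matched = matched or actual_uiv == "T2"
        cls = "matched" if matched else "unmatched"
    return UIVRecommendation(rec.method, rec.recommended_levels, cls)


def mslv_recommendation(result: MSLVResult) -> UIVRecommendation:
    """Wrap an MSLV determination as a single-level recommendation."""
    return UIVRecommendation(method="MSLV", recommended_levels=frozenset({result.mslv}))


# --------------------------------------------------------------------------
# LIV selection rules
# --------------------------------------------------------------------------


def last_touching_vertebra(
    spine: SpineCoronal,
    apex: str | None = None,
    tol: float = DEFAULT_CONTACT_TOL,
) -> str | None:
    """Walking caudally from the main thoracic apex, the first vertebra whose
    body outline touches the CSVL — i.e. the most cephalad vertebra the CSVL
    touches below the curve.  None when no body below the apex touches."""
    from .geometry import mt_apex  # local import to avoid cycle at module load

    apex = apex or mt_apex(spine)
    csvl_x = spine.s1_center.x
    top = spine.vertebrae[0].body_corners[0].y + 1.0
    bot = spine.s1_center.y - 1.0
    csvl = LineString([(csvl_x, bot), (csvl_x, top)])
    for level in lv.ORDER[lv.index(apex) + 1 : lv.index("L5") + 1]:
        if spine.vertebra(level).polygon.distance(csvl) <= tol:
            return level
    return None


def select_liv(
    spine: SpineCoronal,
    subtype: str,
    sv: str | None = None,
    ev: str | None = None,
    tol: float = DEFAULT_CONTACT_TOL,
) -> str:
    """LIV per the study's fixed rules.

    Lenke 2A: the vertebra last touched by the CSVL walking caudally from
    the main thoracic apex.  Lenke 2B/2C: the stable vertebra (SV) when it is
    caudal to the end vertebra (EV), the EV when the EV is caudal, and one
    level below when they coincide.  The result is clamped into T11..L4 so a
    valid MSL can always be constructed.
    """
    if subtype not in {"2A", "2B", "2C"}:
        raise LevelError(f"unknown Lenke subtype {subtype!r}")
    if subtype == "2A":
        liv = last_touching_vertebra(spine, tol=tol)
        if liv is None:
            liv = "L4"
    else:
        if sv is None or ev is None:
            raise LevelError("2B/2C LIV selection requires SV and EV levels")
        si, ei = lv.index(sv), lv.index(ev)
        if si > ei:
            liv = sv
        elif ei > si:
            liv = ev
        else:
            liv = lv.shift(sv, 1)
    lo, hi = lv.index(_LIV_RANGE[0]), lv.index(_LIV_RANGE[1])
    return lv.ORDER[min(max(lv.index(liv), lo), hi)]


# --------------------------------------------------------------------------
# Sensitivity of the MSLV to LIV choice
# --------------------------------------------------------------------------


def mslv_liv_sensitivity(
    spine: SpineCoronal, liv: str, tol: float = DEFAULT_CONTACT_TOL
) -> tuple[bool | None, bool | None]:
    """Whether the MSLV changes when the LIV is hypothetically moved one
    level proximal (first flag) or distal (second flag).  A shift leaving the
    valid LIV range is not evaluable and reported as None."""
    base = determine_mslv(spine, liv, tol).mslv
    flags: list[bool | None] = []
    for step in (-1, +1):
        try:
            shifted = lv.shift(liv, step)
            lo, hi = lv.index(_LIV_RANGE[0]), lv.index(_LIV_RANGE[1])
            if not lo <= lv.index(shifted) <= hi:
                raise LevelError("out of LIV range")
            flags.append(determine_mslv(spine, shifted, tol).mslv != base)
        except LevelError:
            flags.append(None)
    return flags[0], flags[1]
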