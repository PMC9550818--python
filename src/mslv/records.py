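"""Patient records and the cohort JSON interchange format.

One cohort is one JSON document::

    {
      "schema_version": 1,
      "patients": [
        {
          "id": "P001", "age": 14.0, "sex": "F", "lenke_subtype": "2A",
          "bending": {"alpha": 30.0, "beta": 50.0},
          "actual_uiv": "T2", "actual_liv": "L1",
          "srs22r": {"pain": 4.2, ...} | null,
          "films": {
            "preop_coronal": <coronal>, "preop_sagittal": <sagittal>,
            "two_year_coronal": <coronal>, "two_year_sagittal": <sagittal>,
            "first_erect_coronal": <coronal> | null
          }
        }, ...
      ]
    }

A coronal film is ``{"vertebrae": {"C7": {"body": [[x,y],...4], "spinous":
[x,y]}, ...}, "clavicle_left_high": [x,y], "clavicle_right_high": [x,y],
"shoulder_left": [x,y], "shoulder_right": [x,y], "s1_center": [x,y]}``; a
sagittal film is ``{"T1": {"upper": [[x,y],[x,y]], "lower": [[x,y],[x,y]]},
..., "S1": ...}``.  Coordinates are millimetres in the frame documented in
:mod:`mslv.geometry`.

Loading enforces the study's exclusion criteria (UIV cranial to T2; missing
2-year film) by dropping the record with a logged reason rather than
erroring; any malformed field raises :class:`SchemaError` naming the patient
and the JSON path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import levels as lv
from .errors import SchemaError
from .geometry import Point2D, SpineCoronal, SpineSagittal, VertebraCoronal
from .selection import BendingAngles

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

SRS_DOMAINS = ("pain", "function", "self_image", "mental_health", "subtotal", "satisfaction")


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: float
    sex: str  # "F" | "M"
    lenke_subtype: str  # 2A | 2B | 2C
    bending: BendingAngles
    actual_uiv: str
    actual_liv: str
    preop_coronal: SpineCoronal
    preop_sagittal: SpineSagittal
    two_year_coronal: SpineCoronal
    two_year_sagittal: SpineSagittal
    first_erect_coronal: SpineCoronal | None = None
    srs22r: dict | None = None  # opaque numeric domain scores
    srs22r_2yr: dict | None = None


@dataclass
class CohortLoadResult:
    records: list[PatientRecord]
    exclusions: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def _point_to_json(p: Point2D) -> list[float]:
    return [p.x, p.y]


def coronal_to_json(s: SpineCoronal) -> dict:
    return {
        "vertebrae": {
            v.level: {
                "body": [_point_to_json(c) for c in v.body_corners],
                "spinous": _point_to_json(v.spinous_center),
            }
            for v in s.vertebrae
        },
        "clavicle_left_high": _point_to_json(s.clavicle_left_high),
        "clavicle_right_high": _point_to_json(s.clavicle_right_high),
        "shoulder_left": _point_to_json(s.shoulder_left),
        "shoulder_right": _point_to_json(s.shoulder_right),
        "s1_center": _point_to_json(s.s1_center),
    }


def sagittal_to_json(s: SpineSagittal) -> dict:
    return {
        level: {
            "upper": [_point_to_json(p) for p in s.endplates[level]["upper"]],
            "lower": [_point_to_json(p) for p in s.endplates[level]["lower"]],
        }
        for level in lv.SAGITTAL_LEVELS
    }


def record_to_json(r: PatientRecord) -> dict:
    return {
        "id": r.id,
        "age": r.age,
        "sex": r.sex,
        "lenke_subtype": r.lenke_subtype,
        "bending": {"alpha": r.bending.alpha, "beta": r.bending.beta},
        "actual_uiv": r.actual_uiv,
        "actual_liv": r.actual_liv,
        "srs22r": r.srs22r,
        "srs22r_2yr": r.srs22r_2yr,
        "films": {
            "preop_coronal": coronal_to_json(r.preop_coronal),
            "preop_sagittal": sagittal_to_json(r.preop_sagittal),
            "two_year_coronal": coronal_to_json(r.two_year_coronal),
            "two_year_sagittal": sagittal_to_json(r.two_year_sagittal),
            "first_erect_coronal": (
                coronal_to_json(r.first_erect_coronal)
                if r.first_erect_coronal is not None
                else None
            ),
        },
    }


def cohort_to_json(records: list[PatientRecord]) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "patients": [record_to_json(r) for r in records],
    }


def save_cohort(records: list[PatientRecord], path: str | Path) -> None:
    Path(path).write_text(json.dumps(cohort_to_json(records), sort_keys=True))


# --------------------------------------------------------------------------
# Validation / parsing
# --------------------------------------------------------------------------


def _err(pid: str | None, path: str, msg: str) -> SchemaError:
    who = f"patient {pid!r}: " if pid else ""
    return SchemaError(f"{who}{path}: {msg}")


def _parse_point(obj, pid, path) -> Point2D:
    if (
        not isinstance(obj, (list, tuple))
        or len(obj) != 2
        or not all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in obj)
    ):
        raise _err(pid, path, f"expected [x, y] numbers, got {obj!r}")
    try:
        return Point2D(float(obj[0]), float(obj[1]))
    except SchemaError as e:
        raise _err(pid, path, str(e)) from None


def parse_coronal(obj: dict, pid: str | None = None, path: str = "coronal") -> SpineCoronal:
    if not isinstance(obj, dict):
        raise _err(pid, path, "expected an object")
    vobj = obj.get("vertebrae")
    if not isinstance(vobj, dict):
        raise _err(pid, f"{path}.vertebrae", "missing or not an object")
    vertebrae = []
    for level in lv.CORONAL_LEVELS:
        entry = vobj.get(level)
        if not isinstance(entry, dict):
            raise _err(pid, f"{path}.vertebrae.{level}", "missing level")
        body = entry.get("body")
        if not isinstance(body, list) or len(body) != 4:
            raise _err(pid, f"{path}.vertebrae.{level}.body", "expected 4 corner points")
        corners = tuple(
            _parse_point(c, pid, f"{path}.vertebrae.{level}.body[{k}]")
            for k, c in enumerate(body)
        )
        spinous = _parse_point(entry.get("spinous"), pid, f"{path}.vertebrae.{level}.spinous")
        try:
            vertebrae.append(
                VertebraCoronal(level=level, body_corners=corners, spinous_center=spinous)
            )
        except SchemaError as e:
            raise _err(pid, f"{path}.vertebrae.{level}", str(e)) from None
    points = {}
    for name in (
        "clavicle_left_high", "clavicle_right_high",
        "shoulder_left", "shoulder_right", "s1_center",
    ):
        points[name] = _parse_point(obj.get(name), pid, f"{path}.{name}")
    try:
        return SpineCoronal(vertebrae=tuple(vertebrae), **points)
    except SchemaError as e:
        raise _err(pid, path, str(e)) from None


def parse_sagittal(obj: dict, pid: str | None = None, path: str = "sagittal") -> SpineSagittal:
    if not isinstance(obj, dict):
        raise _err(pid, path, "expected an object")
    endplates = {}
    for level in lv.SAGITTAL_LEVELS:
        entry = obj.get(level)
        if not isinstance(entry, dict):
            raise _err(pid, f"{path}.{level}", "missing level")
        plates = {}
        for side in ("upper", "lower"):
            pair = entry.get(side)
            if not isinstance(pair, list) or len(pair) != 2:
                raise _err(pid, f"{path}.{level}.{side}", "expected a pair of points")
            plates[side] = tuple(
                _parse_point(p, pid, f"{path}.{level}.{side}[{k}]") for k, p in enumerate(pair)
            )
        endplates[level] = plates
    try:
        return SpineSagittal(endplates=endplates)
    except SchemaError as e:
        raise _err(pid, path, str(e)) from None


def parse_record(obj: dict) -> PatientRecord:
    if not isinstance(obj, dict):
        raise SchemaError("patient entry is not an object")
    pid = obj.get("id")
    if not isinstance(pid, str) or not pid:
        raise SchemaError("patient id missing or not a string")
    for name in ("age",):
        if not isinstance(obj.get(name), (int, float)):
            raise _err(pid, name, "expected a number")
    if obj.get("sex") not in ("F", "M"):
        raise _err(pid, "sex", "expected 'F' or 'M'")
    if obj.get("lenke_subtype") not in ("2A", "2B", "2C"):
        raise _err(pid, "lenke_subtype", "expected 2A, 2B or 2C")
    bend = obj.get("bending")
    if not isinstance(bend, dict) or not all(
        isinstance(bend.get(k), (int, float)) for k in ("alpha", "beta")
    ):
        raise _err(pid, "bending", "expected {alpha: deg, beta: deg}")
    for name in ("actual_uiv", "actual_liv"):
        try:
            lv.index(obj.get(name))
        except Exception:
            raise _err(pid, name, f"invalid level {obj.get(name)!r}") from None
    films = obj.get("films")
    if not isinstance(films, dict):
        raise _err(pid, "films", "missing films object")
    required = ("preop_coronal", "preop_sagittal", "two_year_coronal", "two_year_sagittal")
    for name in required:
        if films.get(name) is None:
            raise _err(pid, f"films.{name}", "missing required film")
    first_erect = films.get("first_erect_coronal")
    return PatientRecord(
        id=pid,
        age=float(obj["age"]),
        sex=obj["sex"],
        lenke_subtype=obj["lenke_subtype"],
        bending=BendingAngles(alpha=float(bend["alpha"]), beta=float(bend["beta"])),
        actual_uiv=obj["actual_uiv"],
        actual_liv=obj["actual_liv"],
        preop_coronal=parse_coronal(films["preop_coronal"], pid, "films.preop_coronal"),
        preop_sagittal=parse_sagittal(films["preop_sagittal"], pid, "films.preop_sagittal"),
        two_year_coronal=parse_coronal(films["two_year_coronal"], pid, "films.two_year_coronal"),
        two_year_sagittal=parse_sagittal(
            films["two_year_sagittal"], pid, "films.two_year_sagittal"
        ),
        first_erect_coronal=(
            parse_coronal(first_erect, pid, "films.first_erect_coronal")
            if first_erect is not None
            else None
        ),
        srs22r=obj.get("srs22r"),
        srs22r_2yr=obj.get("srs22r_2yr"),
    )


def load_cohort(path: str | Path) -> CohortLoadResult:
    """Load and validate a cohort document, applying the study exclusions.

    Records with a UIV cranial to T2, a UIV caudal to T6, or a missing
    2-year film are dropped with a logged reason and listed in the result's
    ``exclusions``; anything structurally malformed raises
    :class:`SchemaError` naming the patient and field.
    """
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict) or "patients" not in doc:
        raise SchemaError("cohort document must be an object with a 'patients' list")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {doc.get('schema_version')!r}")
    result = CohortLoadResult(records=[])
    for entry in doc["patients"]:
        pid = entry.get("id", "<missing id>") if isinstance(entry, dict) else "<bad entry>"
        # Exclusions are checked before full landmark validation so that an
        # excluded record with an incomplete film set is logged, not fatal.
        if isinstance(entry, dict):
            uiv = entry.get("actual_uiv")
            try:
                uiv_i = lv.index(uiv)
            except Exception:
                uiv_i = None
            if uiv_i is not None and uiv_i < lv.index("T2"):
                reason = f"UIV {uiv} cranial to T2"
                log.info("excluding %s: %s", pid, reason)
                result.exclusions.append((pid, reason))
                continue
            if uiv_i is not None and uiv_i > lv.index("T6"):
                reason = f"UIV {uiv} caudal to T6"
                log.info("excluding %s: %s", pid, reason)
                result.exclusions.append((pid, reason))
                continue
            films = entry.get("films")
            if isinstance(films, dict) and films.get("two_year_coronal") is None:
                reason = "missing 2-year coronal film"
                log.info("excluding %s: %s", pid, reason)
                result.exclusions.append((pid, reason))
                continue
        result.records.append(parse_record(entry))
    return result
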