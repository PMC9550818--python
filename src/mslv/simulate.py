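"""Seeded generator of Lenke-2-like landmark cohorts.

The generator is a stated world, not a fit to data: a double thoracic
deformity is modelled as a smooth per-level endplate-tilt profile whose
extremes sit exactly on the curves' end vertebrae, so the requested proximal
thoracic (PT) and main thoracic (MT) Cobb angles round-trip through the
measurement code by construction.  Lateral body offsets are the integral of
the tilt profile; vertebral bodies are quadrilaterals perpendicular to the
local centerline.  Severe-PT ("deviated") spines get an extra lateral-offset
modifier, escalated until the modified Shinshu line loses all contact in
T3..T8 — the geometric signature of the deviation the MSLV rule clamps to
T2.

Two-year shoulder imbalance is generated *conditionally* on whether the
surgeon's UIV matched the MSLV, with configurable probabilities: the
pipeline's job is detecting that coupling, and conditional generation gives
exact control of the target odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import levels as lv
from .errors import MSLVError
from .geometry import Point2D, SpineCoronal, SpineSagittal, VertebraCoronal
from .records import PatientRecord
from .selection import (
    BendingAngles,
    body_contact_set,
    construct_msl,
    determine_mslv,
    last_touching_vertebra,
    select_liv,
)

# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generator configuration.

    Defaults emulate the printed summary statistics of a 55-patient Lenke 2
    surgical cohort: PT Cobb ~ N(42, 10) deg, MT Cobb ~ N(56, 9) deg, about
    a third of spines with a deviated (severe-PT) modified Shinshu line, the
    surgeon's UIV massed on T2, and 2-year shoulder-imbalance probabilities
    of 0.23 (UIV matched the MSLV) vs 0.55 (unmatched).
    """

    n_patients: int = 55
    seed: int = 0
    pt_cobb_mean: float = 42.0
    pt_cobb_sd: float = 10.0
    mt_cobb_mean: float = 56.0
    mt_cobb_sd: float = 9.0
    pt_apex_level: str = "T3"
    mt_apex_level: str = "T9"
    landmark_noise_sd: float = 0.5  # mm, rigid per-vertebra jitter
    deviation_fraction: float = 0.35
    p_imbalance_matched: float = 0.23
    p_imbalance_unmatched: float = 0.55
    #: surgeon's-choice UIV distribution (mass 43/55 on T2)
    uiv_policy: dict = field(
        default_factory=lambda: {
            "T2": 43 / 55, "T3": 4 / 55, "T4": 6 / 55, "T5": 1 / 55, "T6": 1 / 55,
        }
    )
    #: Lenke 2A / 2B / 2C mix (39 : 10 : 6)
    subtype_probs: tuple[float, float, float] = (39 / 55, 10 / 55, 6 / 55)
    srs_missing_prob: float = 5 / 55

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise MSLVError("n_patients must be >= 1")
        probs = [
            self.deviation_fraction,
            self.p_imbalance_matched,
            self.p_imbalance_unmatched,
            self.srs_missing_prob,
            *self.uiv_policy.values(),
            *self.subtype_probs,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise MSLVError("all probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.uiv_policy.values()), 1.0, abs_tol=1e-9):
            raise MSLVError("uiv_policy must sum to 1")
        if not math.isclose(sum(self.subtype_probs), 1.0, abs_tol=1e-9):
            raise MSLVError("subtype_probs must sum to 1")
        for sd in (self.pt_cobb_sd, self.mt_cobb_sd, self.landmark_noise_sd):
            if sd < 0:
                raise MSLVError("standard deviations must be >= 0")


@dataclass(frozen=True)
class SyntheticPatient:
    """A full patient record plus the generating ground truth.

    The truth dict is for test assertions only and is never consumed by the
    analysis pipeline."""

    record: PatientRecord
    truth: dict


# --------------------------------------------------------------------------
# Geometry assembly helpers
# --------------------------------------------------------------------------

_N = len(lv.CORONAL_LEVELS)  # 18: C7..L5
_DISC = 5.0  # mm

# body height / width grow roughly linearly craniocaudally
_HEIGHTS = np.linspace(22.0, 30.0, _N)
_WIDTHS = np.linspace(30.0, 40.0, _N)

#: deviated-spine lateral modifier, as a fraction of the escalated amplitude.
#: Positive pushes left (the severe PT convexity), negative nudges the
#: mid-thoracic transition right, so escalation always clears T3..T8.
_DEVIATION_PROFILE = {
    "T1": 0.10, "T2": 0.30, "T3": 0.90, "T4": 1.00,
    "T5": 0.85, "T6": 0.60, "T7": -0.30, "T8": -0.15,
}


def _cos_interp(anchors: list[tuple[int, float]], n: int) -> np.ndarray:
    """Piecewise cosine-eased interpolation of (index, value) anchors."""
    out = np.zeros(n)
    for (i0, v0), (i1, v1) in zip(anchors[:-1], anchors[1:]):
        for i in range(i0, i1 + 1):
            t = 0.0 if i1 == i0 else (i - i0) / (i1 - i0)
            out[i] = v0 + (v1 - v0) * (1.0 - math.cos(math.pi * t)) / 2.0
    return out


def _coronal_tilts(pt_cobb: float, mt_cobb: float, pt_apex: str, mt_apex: str) -> np.ndarray:
    """Per-level coronal endplate tilts (degrees, + = left end up).

    The PT curve runs from T1 (tilt +0.25*PT) through its apex to the shared
    end vertebra (tilt 0.25*PT - PT); the MT curve continues to its lower end
    vertebra (tilt 0.25*PT - PT + MT) and the lumbar spine eases back to
    neutral.  The asymmetric split keeps T1 tilt in the clinically observed
    single-digit range while both curve windows still span exactly the
    requested Cobb angles.
    """
    if pt_cobb < 0 or mt_cobb < 0:
        raise MSLVError("Cobb angles must be non-negative")
    if pt_cobb > 0 and mt_cobb < 0.75 * pt_cobb:
        raise MSLVError("double thoracic model requires MT Cobb >= 0.75 * PT Cobb")
    # geometric validity: the lower-end-vertebra tilt (MT - 0.75*PT) must
    # stay well clear of vertical or bodies degenerate
    if mt_cobb - 0.75 * pt_cobb > 70.0:
        raise MSLVError("MT Cobb - 0.75 * PT Cobb must not exceed 70 degrees")
    i_pta = lv.index(pt_apex)
    i_mta = lv.index(mt_apex)
    i_ptu = max(1, i_pta - 2)  # PT upper end vertebra (T1 for apex T3)
    i_shared = min(i_pta + 3, i_mta - 1)  # shared end vertebra (T6)
    i_mtl = min(i_mta + 3, lv.index("L2"))  # MT lower end vertebra (T12)
    i_return = min(i_mta + 7, lv.index("L4"))
    top = 0.25 * pt_cobb
    shared = top - pt_cobb
    bottom = shared + mt_cobb
    anchors = [
        (0, 0.6 * top),
        (i_ptu, top),
        (i_pta, 0.0),
        (i_shared, shared),
        (i_mta, 0.0),
        (i_mtl, bottom),
        (i_return, 0.0),
        (_N - 1, 0.0),
    ]
    return _cos_interp(anchors, _N)


def _centerline(tilts_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid coordinates from the tilt profile (mm; C7 at x=0, y top)."""
    pitch = (_HEIGHTS[:-1] + _HEIGHTS[1:]) / 2.0 + _DISC
    y = np.empty(_N)
    y[0] = float(np.sum(pitch)) + 60.0
    y[1:] = y[0] - np.cumsum(pitch)
    x = np.empty(_N)
    x[0] = 0.0
    t = np.radians(tilts_deg)
    mid = (t[:-1] + t[1:]) / 2.0
    x[1:] = np.cumsum(np.tan(mid) * pitch)
    return x, y


def _assemble_coronal(
    x: np.ndarray,
    y: np.ndarray,
    tilts_deg: np.ndarray,
    s1: tuple[float, float],
    shoulder: dict,
    noise_xy: np.ndarray,
    spinous_noise: np.ndarray,
) -> SpineCoronal:
    vertebrae = []
    t = np.radians(tilts_deg)
    for i, level in enumerate(lv.CORONAL_LEVELS):
        cx, cy = x[i] + noise_xy[i, 0], y[i] + noise_xy[i, 1]
        e = (math.cos(t[i]), math.sin(t[i]))  # endplate direction, +x = left
        u = (-math.sin(t[i]), math.cos(t[i]))  # cranial body axis
        hw, hh = _WIDTHS[i] / 2.0, _HEIGHTS[i] / 2.0
        corners = (
            Point2D(cx + hw * e[0] + hh * u[0], cy + hw * e[1] + hh * u[1]),  # UL
            Point2D(cx - hw * e[0] + hh * u[0], cy - hw * e[1] + hh * u[1]),  # UR
            Point2D(cx - hw * e[0] - hh * u[0], cy - hw * e[1] - hh * u[1]),  # LR
            Point2D(cx + hw * e[0] - hh * u[0], cy + hw * e[1] - hh * u[1]),  # LL
        )
        spinous = Point2D(cx + spinous_noise[i, 0], cy + spinous_noise[i, 1])
        vertebrae.append(
            VertebraCoronal(level=level, body_corners=corners, spinous_center=spinous)
        )
    return SpineCoronal(
        vertebrae=tuple(vertebrae),
        s1_center=Point2D(*s1),
        **shoulder,
    )


def _rotate_about(
    x: np.ndarray, y: np.ndarray, pivot: tuple[float, float], angle_rad: float
) -> tuple[np.ndarray, np.ndarray]:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    dx, dy = x - pivot[0], y - pivot[1]
    return pivot[0] + c * dx - s * dy, pivot[1] + s * dx + c * dy


def _sagittal(
    tk: float, ll: float, rng: np.random.Generator, noise_sd: float
) -> SpineSagittal:
    """Sagittal endplates from a kyphosis/lordosis tilt template."""
    n = len(lv.SAGITTAL_LEVELS)  # T1..S1
    idx = {level: i for i, level in enumerate(lv.SAGITTAL_LEVELS)}
    anchors = [
        (idx["T1"], -tk / 2.0 - 1.0),
        (idx["T5"], -tk / 2.0),
        (idx["T12"], tk / 2.0),
        (idx["S1"], tk / 2.0 - ll),
    ]
    tilts = np.zeros(n)
    for (i0, v0), (i1, v1) in zip(anchors[:-1], anchors[1:]):
        for i in range(i0, i1 + 1):
            t = 0.0 if i1 == i0 else (i - i0) / (i1 - i0)
            tilts[i] = v0 + (v1 - v0) * (1.0 - math.cos(math.pi * t)) / 2.0
    heights = np.concatenate([np.linspace(23.0, 30.0, n - 1), [12.0]])  # S1 thin
    pitch = (heights[:-1] + heights[1:]) / 2.0 + _DISC
    y = np.empty(n)
    y[0] = float(np.sum(pitch)) + 40.0
    y[1:] = y[0] - np.cumsum(pitch)
    t = np.radians(tilts)
    mid = (t[:-1] + t[1:]) / 2.0
    x = np.empty(n)
    x[0] = 0.0
    x[1:] = np.cumsum(np.tan(mid) * pitch)
    jitter = rng.normal(0.0, noise_sd, size=(n, 2))
    endplates = {}
    for i, level in enumerate(lv.SAGITTAL_LEVELS):
        cx, cy = x[i] + jitter[i, 0], y[i] + jitter[i, 1]
        e = (math.cos(t[i]), math.sin(t[i]))
        u = (-math.sin(t[i]), math.cos(t[i]))
        hw, hh = 15.0, heights[i] / 2.0
        endplates[level] = {
            "upper": (
                Point2D(cx - hw * e[0] + hh * u[0], cy - hw * e[1] + hh * u[1]),
                Point2D(cx + hw * e[0] + hh * u[0], cy + hw * e[1] + hh * u[1]),
            ),
            "lower": (
                Point2D(cx - hw * e[0] - hh * u[0], cy - hw * e[1] - hh * u[1]),
                Point2D(cx + hw * e[0] - hh * u[0], cy + hw * e[1] - hh * u[1]),
            ),
        }
    return SpineSagittal(endplates=endplates)


# --------------------------------------------------------------------------
# Public generators
# --------------------------------------------------------------------------


def generate_spine(
    pt_cobb: float,
    mt_cobb: float,
    rng: np.random.Generator | None = None,
    *,
    pt_apex: str = "T3",
    mt_apex: str = "T9",
    landmark_noise_sd: float = 0.5,
    deviated: bool = False,
    rsh: float | None = None,
    ca: float | None = None,
    tk: float = 13.0,
    ll: float = 47.0,
    c7_offset: float | None = None,
    contact_tol: float = 0.1,
) -> tuple[SpineCoronal, SpineSagittal]:
    """Generate one film pair with the requested curve magnitudes.

    ``rsh`` fixes the 2-point shoulder height difference exactly (mm); when
    None it is coupled to the realized T1 tilt plus noise.  ``c7_offset`` is
    the signed horizontal C7-plumb-line-to-CSVL offset (mm); None draws
    N(0, 7).  ``deviated=True`` escalates a proximal lateral modifier until
    the modified Shinshu line loses all body contact in T3..T8.
    """
    rng = rng or np.random.default_rng(0)
    tilts = _coronal_tilts(pt_cobb, mt_cobb, pt_apex, mt_apex)
    # small per-vertebra orientation jitter (digitization), kept well below
    # the 1-degree Cobb round-trip budget
    tilts = tilts + rng.normal(0.0, 0.1, size=_N)
    x, y = _centerline(tilts)

    # S1 reference sits one segment below L5, on the local centerline.
    s1_y = y[-1] - (_HEIGHTS[-1] / 2.0 + _DISC + 6.0)
    s1_x = x[-1]

    # Rigidly rotate about S1 so the C7 plumb line lands at the requested
    # horizontal offset from the CSVL (trunk-shift realism); tilts rotate too.
    delta = float(rng.normal(0.0, 7.0)) if c7_offset is None else float(c7_offset)
    v = np.hypot(x[0] - s1_x, y[0] - s1_y)
    delta = float(np.clip(delta, -0.2 * v, 0.2 * v))
    phi_now = math.atan2(x[0] - s1_x, y[0] - s1_y)
    rot = math.asin(delta / v) - phi_now
    x, y = _rotate_about(x, y, (s1_x, s1_y), rot)
    tilts = tilts + math.degrees(rot)

    noise_xy = rng.normal(0.0, landmark_noise_sd, size=(_N, 2))
    spinous_noise = rng.normal(0.0, landmark_noise_sd, size=(_N, 2))
    s1_noise = rng.normal(0.0, landmark_noise_sd, size=2)
    s1 = (s1_x + s1_noise[0], s1_y + s1_noise[1])

    dev_amp = 0.0
    profile = np.array(
        [_DEVIATION_PROFILE.get(level, 0.0) for level in lv.CORONAL_LEVELS]
    )

    def build(amp: float) -> SpineCoronal:
        xs = x + amp * profile
        # shoulder girdle: RSH realized exactly, clavicular angle coupled to
        # T1 tilt (placeholder points; replaced after rsh/ca resolved below)
        return _assemble_coronal(
            xs, y, tilts, s1, shoulder_points, noise_xy, spinous_noise
        )

    # provisional shoulder points (recomputed once rsh/ca are final)
    y_t1 = y[1]
    shoulder_points = {
        "clavicle_left_high": Point2D(110.0, y_t1 + 12.0),
        "clavicle_right_high": Point2D(-110.0, y_t1 + 12.0),
        "shoulder_left": Point2D(150.0, y_t1 + 25.0),
        "shoulder_right": Point2D(-150.0, y_t1 + 25.0),
    }

    spine = build(0.0)
    if deviated:
        t3_t8 = set(lv.span("T3", "T8"))
        nominal_liv = last_touching_vertebra(spine) or "L1"
        if lv.index(nominal_liv) < lv.index("T11"):
            nominal_liv = "T11"
        amp = 25.0
        for _ in range(18):
            trial = build(amp)
            seg = construct_msl(trial, nominal_liv)
            if not t3_t8.intersection(body_contact_set(trial, seg, contact_tol)):
                break
            amp *= 1.3
        dev_amp = amp
        spine = build(amp)

    # final shoulder girdle from the realized T1 tilt
    from .geometry import t1_tilt as _t1_tilt  # avoid top-level cycle

    t1 = _t1_tilt(spine)
    if rsh is None:
        rsh = float(rng.normal(1.0 * t1, 6.0))
    if ca is None:
        ca = float(rng.normal(0.35 * t1, 1.5))
    half_ca = 110.0 * math.tan(math.radians(ca))
    shoulder_points = {
        "clavicle_left_high": Point2D(110.0, y_t1 + 12.0 + half_ca),
        "clavicle_right_high": Point2D(-110.0, y_t1 + 12.0 - half_ca),
        "shoulder_left": Point2D(150.0, y_t1 + 25.0 + rsh / 2.0),
        "shoulder_right": Point2D(-150.0, y_t1 + 25.0 - rsh / 2.0),
    }
    coronal = build(dev_amp)
    sagittal = _sagittal(tk, ll, rng, landmark_noise_sd)
    return coronal, sagittal


def _stable_vertebra(spine: SpineCoronal) -> str:
    """Most cephalad vertebra whose body centroid stays near the CSVL in the
    unbroken run walking up from L5 (stable-vertebra surrogate)."""
    csvl_x = spine.s1_center.x
    stable = "L5"
    for level in reversed(lv.span("T8", "L5")):
        v = spine.vertebra(level)
        half_w = abs(v.body_corners[0].x - v.body_corners[1].x) / 2.0
        if abs(v.centroid.x - csvl_x) <= half_w / 2.0:
            stable = level
        else:
            break
    return stable


def _srs_scores(rng: np.random.Generator, post: bool) -> dict:
    if post:
        spec = {
            "pain": (4.4, 0.7), "function": (4.7, 0.3), "self_image": (4.1, 0.6),
            "mental_health": (4.4, 0.6), "satisfaction": (4.2, 0.7),
        }
    else:
        spec = {
            "pain": (4.2, 0.7), "function": (4.4, 0.5), "self_image": (2.8, 0.6),
            "mental_health": (3.9, 0.8),
        }
    out = {k: float(np.clip(rng.normal(m, s), 1.0, 5.0)) for k, (m, s) in spec.items()}
    core = ["pain", "function", "self_image", "mental_health"]
    out["subtotal"] = float(np.mean([out[k] for k in core]))
    return out


def generate_patient(
    cfg: SyntheticConfig, rng: np.random.Generator, pid: str
) -> SyntheticPatient:
    pt = float(np.clip(rng.normal(cfg.pt_cobb_mean, cfg.pt_cobb_sd), 20.0, 75.0))
    mt = float(
        np.clip(rng.normal(cfg.mt_cobb_mean, cfg.mt_cobb_sd),
                0.8 * pt, min(90.0, 0.75 * pt + 65.0))
    )
    subtype = str(rng.choice(["2A", "2B", "2C"], p=list(cfg.subtype_probs)))
    deviated = bool(rng.random() < cfg.deviation_fraction)
    tk = float(np.clip(rng.normal(13.5, 8.0), -5.0, 40.0))
    ll = float(np.clip(rng.normal(47.0, 9.0), 20.0, 75.0))

    pre_cor, pre_sag = generate_spine(
        pt, mt, rng,
        pt_apex=cfg.pt_apex_level, mt_apex=cfg.mt_apex_level,
        landmark_noise_sd=cfg.landmark_noise_sd, deviated=deviated,
        tk=tk, ll=ll,
    )

    if subtype == "2A":
        liv = select_liv(pre_cor, "2A")
    else:
        from .geometry import auto_end_vertebrae

        ev = auto_end_vertebrae(pre_cor, "MT")[1]
        sv = _stable_vertebra(pre_cor)
        liv = select_liv(pre_cor, subtype, sv=sv, ev=ev)

    policy_levels = list(cfg.uiv_policy.keys())
    uiv = str(rng.choice(policy_levels, p=[cfg.uiv_policy[k] for k in policy_levels]))

    mslv_res = determine_mslv(pre_cor, liv)
    matched = uiv == mslv_res.mslv
    p_imb = cfg.p_imbalance_matched if matched else cfg.p_imbalance_unmatched
    imbalanced = bool(rng.random() < p_imb)
    sign = -1.0 if rng.random() < 0.5 else 1.0
    if imbalanced:
        rsh_2yr = sign * (10.0 + float(rng.exponential(5.0)))
    else:
        rsh_2yr = sign * float(rng.uniform(0.0, 9.5))

    pt_corr = float(np.clip(rng.normal(0.52, 0.17), 0.15, 0.85))
    mt_corr = float(np.clip(rng.normal(0.64, 0.13), 0.20, 0.90))
    pt_post = pt * (1.0 - pt_corr)
    mt_post = max(mt * (1.0 - mt_corr), 0.8 * pt_post + 2.0)

    post_cor, post_sag = generate_spine(
        pt_post, mt_post, rng,
        pt_apex=cfg.pt_apex_level, mt_apex=cfg.mt_apex_level,
        landmark_noise_sd=cfg.landmark_noise_sd, deviated=False,
        rsh=rsh_2yr, tk=tk + float(rng.normal(6.0, 3.0)), ll=ll,
    )
    erect_cor, _ = generate_spine(
        pt_post, mt_post, rng,
        pt_apex=cfg.pt_apex_level, mt_apex=cfg.mt_apex_level,
        landmark_noise_sd=cfg.landmark_noise_sd, deviated=False,
        tk=tk, ll=ll,
    )

    srs_missing = rng.random() < cfg.srs_missing_prob
    record = PatientRecord(
        id=pid,
        age=float(np.clip(rng.normal(14.3, 1.9), 11.0, 20.0)),
        sex="F" if rng.random() < 45 / 55 else "M",
        lenke_subtype=subtype,
        bending=BendingAngles(
            alpha=float(max(5.0, 0.68 * pt + rng.normal(0.0, 4.0))),
            beta=float(max(5.0, 0.55 * mt + rng.normal(0.0, 4.0))),
        ),
        actual_uiv=uiv,
        actual_liv=liv,
        preop_coronal=pre_cor,
        preop_sagittal=pre_sag,
        two_year_coronal=post_cor,
        two_year_sagittal=post_sag,
        first_erect_coronal=erect_cor,
        srs22r=None if srs_missing else _srs_scores(rng, post=False),
        srs22r_2yr=None if srs_missing else _srs_scores(rng, post=True),
    )
    truth = {
        "pt_cobb": pt,
        "mt_cobb": mt,
        "pt_cobb_2yr": pt_post,
        "mt_cobb_2yr": mt_post,
        "deviated_intent": deviated,
        "deviated": mslv_res.deviated,
        "mslv": mslv_res.mslv,
        "liv": liv,
        "uiv": uiv,
        "matched": matched,
        "imbalanced": imbalanced,
        "rsh_2yr": rsh_2yr,
        "subtype": subtype,
    }
    return SyntheticPatient(record=record, truth=truth)


def generate_cohort(cfg: SyntheticConfig) -> list[SyntheticPatient]:
    """Generate a fully reproducible cohort: identical config and seed give
    byte-identical serialized output."""
    rng = np.random.default_rng(cfg.seed)
    return [
        generate_patient(cfg, rng, f"P{i + 1:03d}") for i in range(cfg.n_patients)
    ]
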