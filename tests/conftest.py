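"""Shared fixtures and independent geometric oracles.

``build_coronal``/``build_sagittal`` construct landmark sets directly from
per-level tilt/offset dictionaries, independently of the package's synthetic
generator, so geometry and selection tests control their inputs exactly.
``sampling_contact_oracle`` re-derives segment-body contact by dense point
sampling (point-in-polygon plus point-to-edge distance in plain numpy),
independent of the shapely-based implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mslv import levels as lv
from mslv.geometry import Point2D, SpineCoronal, SpineSagittal, VertebraCoronal

BODY_H = 25.0
BODY_W = 34.0
PITCH = 30.0
TOP_Y = 540.0


def build_coronal(
    tilts: dict | None = None,
    offsets: dict | None = None,
    rsh: float = 0.0,
    ca: float = 0.0,
    s1_x: float | None = None,
    mirror: bool = False,
) -> SpineCoronal:
    """Coronal film with per-level endplate tilts (deg, + = left up) and
    lateral centroid offsets (mm, + = patient left); everything else neutral.
    ``mirror=True`` reflects the whole construction about the vertical axis
    (tilts, offsets, shoulder sides all flip)."""
    tilts = dict(tilts or {})
    offsets = dict(offsets or {})
    sgn = -1.0 if mirror else 1.0
    vertebrae = []
    for i, level in enumerate(lv.CORONAL_LEVELS):
        cy = TOP_Y - i * PITCH
        cx = sgn * offsets.get(level, 0.0)
        t = math.radians(sgn * tilts.get(level, 0.0))
        e = (math.cos(t), math.sin(t))
        u = (-math.sin(t), math.cos(t))
        hw, hh = BODY_W / 2.0, BODY_H / 2.0
        corners = (
            Point2D(cx + hw * e[0] + hh * u[0], cy + hw * e[1] + hh * u[1]),
            Point2D(cx - hw * e[0] + hh * u[0], cy - hw * e[1] + hh * u[1]),
            Point2D(cx - hw * e[0] - hh * u[0], cy - hw * e[1] - hh * u[1]),
            Point2D(cx + hw * e[0] - hh * u[0], cy + hw * e[1] - hh * u[1]),
        )
        vertebrae.append(
            VertebraCoronal(level=level, body_corners=corners, spinous_center=Point2D(cx, cy))
        )
    y_t1 = TOP_Y - PITCH
    half_ca = 110.0 * math.tan(math.radians(sgn * ca))
    return SpineCoronal(
        vertebrae=tuple(vertebrae),
        clavicle_left_high=Point2D(110.0, y_t1 + 12.0 + half_ca),
        clavicle_right_high=Point2D(-110.0, y_t1 + 12.0 - half_ca),
        shoulder_left=Point2D(150.0, y_t1 + 25.0 + sgn * rsh / 2.0),
        shoulder_right=Point2D(-150.0, y_t1 + 25.0 - sgn * rsh / 2.0),
        s1_center=Point2D(sgn * (s1_x if s1_x is not None else 0.0), TOP_Y - 18 * PITCH),
    )


def build_sagittal(tilts: dict | None = None) -> SpineSagittal:
    """Sagittal film with parallel per-level endplates at the given tilts."""
    tilts = dict(tilts or {})
    endplates = {}
    for i, level in enumerate(lv.SAGITTAL_LEVELS):
        cy = TOP_Y - i * PITCH
        t = math.radians(tilts.get(level, 0.0))
        e = (math.cos(t), math.sin(t))
        u = (-math.sin(t), math.cos(t))
        hw, hh = 15.0, 11.0
        endplates[level] = {
            "upper": (
                Point2D(-hw * e[0] + hh * u[0], cy - hw * e[1] + hh * u[1]),
                Point2D(hw * e[0] + hh * u[0], cy + hw * e[1] + hh * u[1]),
            ),
            "lower": (
                Point2D(-hw * e[0] - hh * u[0], cy - hw * e[1] - hh * u[1]),
                Point2D(hw * e[0] - hh * u[0], cy + hw * e[1] - hh * u[1]),
            ),
        }
    return SpineSagittal(endplates=endplates)


# --------------------------------------------------------------------------
# Independent contact oracle
# --------------------------------------------------------------------------


def _point_polygon_distance(px: np.ndarray, py: np.ndarray, corners) -> np.ndarray:
    """Distance from each sample point to a convex quadrilateral (0 inside)."""
    xs = np.array([c.x for c in corners])
    ys = np.array([c.y for c in corners])
    inside = np.ones_like(px, dtype=bool)
    dmin = np.full_like(px, np.inf, dtype=float)
    for k in range(4):
        x0, y0 = xs[k], ys[k]
        x1, y1 = xs[(k + 1) % 4], ys[(k + 1) % 4]
        ex, ey = x1 - x0, y1 - y0
        # CCW polygon: inside iff every cross product is >= 0
        cross = ex * (py - y0) - ey * (px - x0)
        inside &= cross >= 0
        # distance to the edge segment
        L2 = ex * ex + ey * ey
        t = np.clip(((px - x0) * ex + (py - y0) * ey) / L2, 0.0, 1.0)
        dx, dy = px - (x0 + t * ex), py - (y0 + t * ey)
        dmin = np.minimum(dmin, np.hypot(dx, dy))
    return np.where(inside, 0.0, dmin)


def sampling_contact_oracle(
    spine: SpineCoronal, liv: str, tol: float = 0.1, n_samples: int = 10_000
) -> tuple[str, ...]:
    """Contact set by dense sampling: 10^4 points along the MSL, each tested
    against every body polygon by point-in-polygon + point-to-edge distance."""
    start = spine.vertebra(liv).spinous_center
    end = spine.vertebra("C7").spinous_center
    ts = np.linspace(0.0, 1.0, n_samples)
    px = start.x + ts * (end.x - start.x)
    py = start.y + ts * (end.y - start.y)
    out = []
    for level in lv.ORDER[1 : lv.index(liv)]:
        corners = spine.vertebra(level).body_corners
        # corner order UL, UR, LR, LL is counter-clockwise in (x, y)
        d = _point_polygon_distance(px, py, corners)
        if float(d.min()) <= tol:
            out.append(level)
    return tuple(out)


def reference_mslv(contacts: tuple[str, ...], liv: str) -> tuple[str, bool]:
    """Plain re-statement of the MSLV traversal rule, applied to an
    externally supplied contact set (used with the sampling oracle)."""
    idx = [lv.index(c) for c in contacts]
    runs: list[list[int]] = []
    for i in idx:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    liv_i = lv.index(liv)
    liv_run = None
    if runs and runs[-1][-1] == liv_i - 1:
        liv_run = runs.pop()
    if liv_run is not None and liv_run[0] == lv.index("T1"):
        return "T2", False
    if not runs:
        return "T2", True
    cand = runs[-1][-1]
    t3, t8 = lv.index("T3"), lv.index("T8")
    if cand < t3 and not any(t3 <= i <= t8 for i in idx):
        mslv_i = max(idx[0], lv.index("T2"))
        return lv.ORDER[mslv_i], True
    cand = max(cand, lv.index("T2"))
    cand = min(cand, liv_i - 1)
    return lv.ORDER[cand], False


@pytest.fixture
def straight_spine() -> SpineCoronal:
    return build_coronal()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
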