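"""MSL/MSLV algorithm and UIV recommendation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from mslv import levels as lv
from mslv.errors import ExclusionError, LevelError
from mslv.geometry import Point2D, RadiographicParams, SpineCoronal, VertebraCoronal
from mslv.selection import (
    BendingAngles,
    body_contact_set,
    classify_match,
    construct_msl,
    determine_mslv,
    mslv_liv_sensitivity,
    mslv_recommendation,
    recommend_ilharreborde,
    recommend_lenke,
    recommend_trobisch,
    select_liv,
)
from mslv.simulate import generate_spine

from conftest import build_coronal, reference_mslv, sampling_contact_oracle


def _params(rsh=0.0, t1=0.0):
    return RadiographicParams(
        pt_cobb=40, mt_cobb=55, c7pl_csvl=0.5, ca=0.0, t1_tilt=t1, rsh=rsh, mt_avt=4.0
    )


class TestConstructMSL:
    def test_endpoints_are_spinous_centers(self, straight_spine):
        seg = construct_msl(straight_spine, "L2")
        assert seg.start == straight_spine.vertebra("L2").spinous_center
        assert seg.end == straight_spine.vertebra("C7").spinous_center

    @pytest.mark.parametrize("liv", ["T10", "L5", "C7"])
    def test_liv_out_of_range_rejected(self, straight_spine, liv):
        with pytest.raises(LevelError):
            construct_msl(straight_spine, liv)

    def test_straight_spine_vertical_segment(self, straight_spine):
        seg = construct_msl(straight_spine, "L1")
        assert seg.start.x == pytest.approx(seg.end.x)

    def test_mirrored_spine_mirrored_segment(self):
        plain = build_coronal(offsets={"L1": 8.0})
        mirrored = build_coronal(offsets={"L1": 8.0}, mirror=True)
        sp, sm = construct_msl(plain, "L1"), construct_msl(mirrored, "L1")
        assert sm.start.x == pytest.approx(-sp.start.x)


class TestBodyContactSet:
    def test_straight_colinear_spine_touches_everything(self, straight_spine):
        seg = construct_msl(straight_spine, "L1")
        assert body_contact_set(straight_spine, seg) == lv.span("T1", "T12")

    def test_translated_column_touches_nothing(self):
        spine = build_coronal(offsets={l: -50.0 for l in lv.CORONAL_LEVELS})
        # MSL endpoints follow the spinous centers, so shift them back to
        # simulate a segment 50 mm away from every body
        seg = construct_msl(spine, "L1")
        from mslv.selection import MSLSegment

        seg = MSLSegment(
            start=Point2D(seg.start.x + 50.0, seg.start.y),
            end=Point2D(seg.end.x + 50.0, seg.end.y),
            liv="L1",
        )
        assert body_contact_set(spine, seg) == ()

    def test_two_arc_spine_matches_sampling_oracle(self, rng):
        cor, _ = generate_spine(45.0, 58.0, rng)
        liv = "L1"
        seg = construct_msl(cor, liv)
        assert body_contact_set(cor, seg) == sampling_contact_oracle(cor, liv)


class TestDetermineMSLV:
    def test_straight_spine_clamps_to_t2(self, straight_spine):
        res = determine_mslv(straight_spine, "L1")
        assert (res.mslv, res.deviated) == ("T2", False)

    def test_mild_pt_first_reentry_level(self):
        """A mild proximal curve whose segment re-enters the column at T5."""
        offsets = {"T3": 25.0, "T4": 22.0, "T5": 16.0, "T6": 25.0, "T7": 30.0,
                   "T8": 30.0, "T9": 25.0, "T10": 22.0, "T11": 20.0}
        spine = build_coronal(offsets=offsets)
        res = determine_mslv(spine, "L1")
        assert res.mslv == "T5"
        assert not res.deviated
        oracle_mslv, oracle_dev = reference_mslv(
            sampling_contact_oracle(spine, "L1"), "L1"
        )
        assert (res.mslv, res.deviated) == (oracle_mslv, oracle_dev)

    def test_severe_pt_deviates_to_t2(self):
        """No contact anywhere in T3..T8, contact at T2: deviated, MSLV T2."""
        offsets = {"T2": 10.0, "T3": 45.0, "T4": 60.0, "T5": 60.0, "T6": 50.0,
                   "T7": -40.0, "T8": -45.0, "T9": -40.0, "T10": -30.0, "T11": -25.0}
        spine = build_coronal(offsets=offsets)
        res = determine_mslv(spine, "L1")
        assert res.mslv == "T2"
        assert res.deviated
        assert not set(lv.span("T3", "T8")).intersection(res.contact_levels)

    def test_no_contact_above_liv_run(self):
        offsets = {l: 60.0 for l in lv.span("T1", "T10")}
        spine = build_coronal(offsets=offsets)
        res = determine_mslv(spine, "L1")
        assert (res.mslv, res.deviated) == ("T2", True)

    def test_output_range_invariant(self, rng):
        """MSLV always lies in [T2, level cranial to LIV]."""
        for _ in range(30):
            pt = float(rng.uniform(20, 70))
            mt = float(rng.uniform(max(40.0, 0.8 * pt), 85))
            liv = str(rng.choice(["T12", "L1", "L2", "L3"]))
            cor, _ = generate_spine(pt, mt, rng, deviated=bool(rng.random() < 0.4))
            res = determine_mslv(cor, liv)
            assert lv.index("T2") <= lv.index(res.mslv) < lv.index(liv)

    @given(scale=st_h.floats(0.3, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        """Uniform scaling of all landmarks leaves the MSLV unchanged."""
        offsets = {"T3": 25.0, "T4": 22.0, "T5": 16.0, "T6": 25.0, "T7": 30.0,
                   "T8": 30.0, "T9": 25.0, "T10": 22.0, "T11": 20.0}
        spine = build_coronal(offsets=offsets)

        def scaled(s: SpineCoronal) -> SpineCoronal:
            def sp(p):
                return Point2D(p.x * scale, p.y * scale)

            return SpineCoronal(
                vertebrae=tuple(
                    VertebraCoronal(
                        level=v.level,
                        body_corners=tuple(sp(c) for c in v.body_corners),
                        spinous_center=sp(v.spinous_center),
                    )
                    for v in s.vertebrae
                ),
                clavicle_left_high=sp(s.clavicle_left_high),
                clavicle_right_high=sp(s.clavicle_right_high),
                shoulder_left=sp(s.shoulder_left),
                shoulder_right=sp(s.shoulder_right),
                s1_center=sp(s.s1_center),
            )

        base = determine_mslv(spine, "L1", tol=0.1)
        other = determine_mslv(scaled(spine), "L1", tol=0.1 * scale)
        assert (base.mslv, base.deviated) == (other.mslv, other.deviated)


class TestRecommenders:
    def test_lenke_left_elevated(self):
        assert recommend_lenke(_params(rsh=8.0)).recommended_levels == {"T2"}

    def test_lenke_complement(self):
        assert recommend_lenke(_params(rsh=-8.0)).recommended_levels == {"T3", "T4", "T5", "T6"}

    def test_lenke_zero_rsh_not_elevated(self):
        assert "T2" not in recommend_lenke(_params(rsh=0.0)).recommended_levels

    @pytest.mark.parametrize(
        "alpha, beta, t1, rsh_v, expected",
        [
            # row alpha - beta/2 <= 15 across the three columns
            (30, 50, 6.0, 12.0, {"T4", "T5", "T6"}),
            (30, 50, 6.0, -12.0, {"T2", "T3"}),
            (30, 50, -4.0, -10.0, {"T1", "T2"}),
            # row alpha - beta/2 > 15
            (50, 50, 6.0, 12.0, {"T2", "T3"}),
            (50, 50, 6.0, -12.0, {"T1", "T2"}),
            (50, 50, -4.0, -10.0, {"T1", "T2"}),
            # boundaries: index exactly 15 -> "<" row; zero sign -> opposite
            (40, 50, 6.0, 12.0, {"T4", "T5", "T6"}),
            (30, 50, 0.0, 12.0, {"T2", "T3"}),
        ],
    )
    def test_ilharreborde_cells(self, alpha, beta, t1, rsh_v, expected):
        rec = recommend_ilharreborde(BendingAngles(alpha, beta), t1, rsh_v)
        assert rec.recommended_levels == expected

    def test_trobisch_always_t2(self):
        assert recommend_trobisch().recommended_levels == {"T2"}


class TestClassifyMatch:
    def test_mslv_proximal_group(self):
        from mslv.selection import MSLVResult

        res = MSLVResult("T4", False, ("T4",))
        cls = classify_match("T2", mslv_recommendation(res), res)
        assert cls.match_class == "proximal"

    def test_mslv_matched_and_distal(self):
        from mslv.selection import MSLVResult

        res = MSLVResult("T4", False, ("T4",))
        assert classify_match("T4", mslv_recommendation(res), res).match_class == "matched"
        assert classify_match("T5", mslv_recommendation(res), res).match_class == "distal"

    def test_ilharreborde_t1_allowance(self):
        rec = recommend_ilharreborde(BendingAngles(50, 50), -4.0, -10.0)
        assert rec.recommended_levels == {"T1", "T2"}
        assert classify_match("T2", rec).match_class == "matched"

    def test_trobisch_unmatched(self):
        assert classify_match("T3", recommend_trobisch()).match_class == "unmatched"

    def test_uiv_above_t2_excluded(self):
        with pytest.raises(ExclusionError):
            classify_match("T1", recommend_trobisch())

    def test_membership_always_matches(self):
        """For every method, an actual UIV inside the recommended set is
        classified as matched."""
        for rec in (
            recommend_lenke(_params(rsh=5.0)),
            recommend_lenke(_params(rsh=-5.0)),
            recommend_ilharreborde(BendingAngles(30, 50), 6.0, 12.0),
            recommend_trobisch(),
        ):
            for level in rec.recommended_levels:
                if lv.index(level) < lv.index("T2"):
                    continue  # T1 cannot be an actual UIV here
                assert classify_match(level, rec).match_class == "matched"


class TestSelectLIV:
    @pytest.mark.parametrize(
        "subtype, sv, ev, expected",
        [
            ("2B", "L2", "L1", "L2"),  # SV below EV -> SV
            ("2C", "L1", "L3", "L3"),  # EV below SV -> EV
            ("2B", "L1", "L1", "L2"),  # SV == EV -> one level below
        ],
    )
    def test_sv_ev_rules(self, straight_spine, subtype, sv, ev, expected):
        assert select_liv(straight_spine, subtype, sv=sv, ev=ev) == expected

    def test_2a_last_touching_vertebra(self):
        # MT curve deviating right, returning to the CSVL at L1
        offsets = {"T7": -30.0, "T8": -40.0, "T9": -45.0, "T10": -40.0,
                   "T11": -32.0, "T12": -22.0, "L1": -8.0}
        spine = build_coronal(offsets=offsets)
        assert select_liv(spine, "2A") == "L1"

    def test_2a_agrees_with_manual_walk(self, rng):
        from mslv.geometry import mt_apex
        from mslv.selection import last_touching_vertebra
        from shapely.geometry import LineString

        for _ in range(10):
            cor, _ = generate_spine(
                float(rng.uniform(25, 60)), float(rng.uniform(45, 75)), rng
            )
            liv = select_liv(cor, "2A")
            # manual walk: first level below the apex whose polygon comes
            # within tolerance of the vertical through s1
            csvl = LineString(
                [(cor.s1_center.x, -1000.0), (cor.s1_center.x, 1000.0)]
            )
            apex = mt_apex(cor)
            walked = None
            for level in lv.span(lv.shift(apex, 1), "L5"):
                if cor.vertebra(level).polygon.distance(csvl) <= 0.1:
                    walked = level
                    break
            expected = walked or "L4"
            lo, hi = lv.index("T11"), lv.index("L4")
            expected = lv.ORDER[min(max(lv.index(expected), lo), hi)]
            assert liv == expected


class TestSensitivity:
    def test_straight_spine_insensitive(self, straight_spine):
        assert mslv_liv_sensitivity(straight_spine, "L1") == (False, False)

    def test_range_edges_not_evaluable(self, straight_spine):
        prox, dist = mslv_liv_sensitivity(straight_spine, "T11")
        assert prox is None and dist is False
        prox, dist = mslv_liv_sensitivity(straight_spine, "L4")
        assert prox is False and dist is None

    def test_mirror_symmetric_flags(self):
        offsets = {"T3": 25.0, "T4": 22.0, "T5": 16.0, "T6": 25.0, "T7": 30.0,
                   "T8": 30.0, "T9": 25.0, "T10": 22.0, "T11": 20.0}
        a = build_coronal(offsets=offsets)
        b = build_coronal(offsets=offsets, mirror=True)
        assert mslv_liv_sensitivity(a, "L1") == mslv_liv_sensitivity(b, "L1")

    def test_detects_change_on_shift(self, rng):
        """The flags agree with direct recomputation at the shifted LIVs."""
        for _ in range(10):
            cor, _ = generate_spine(
                float(rng.uniform(25, 65)), float(rng.uniform(45, 80)), rng,
                deviated=bool(rng.random() < 0.4),
            )
            base = determine_mslv(cor, "L1").mslv
            prox, dist = mslv_liv_sensitivity(cor, "L1")
            assert prox == (determine_mslv(cor, "T12").mslv != base)
            assert dist == (determine_mslv(cor, "L2").mslv != base)
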