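import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_snapshot
from swinescore.scores import (DEFAULT_SNORT_RUBRIC, SnortRubric,
                               VitalsSnapshot, evaluate_sirs, news2_points,
                               news2_total, snort_score, sofa_component,
                               sofa_total)


class TestSnapshotValidation:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            make_snapshot(hr=-5.0)
        with pytest.raises(ValueError):
            make_snapshot(spo2=120.0)
        with pytest.raises(ValueError):
            make_snapshot(snort=1.0)
        with pytest.raises(ValueError):
            VitalsSnapshot(animal_id="x", time_h=0.0, phase="dawn")

    def test_missing_values_allowed(self):
        snap = VitalsSnapshot(animal_id="x", time_h=0.0, phase="day", hr=100.0)
        assert snap.wbc is None


class TestSirs:
    def test_peak_tachycardia_with_leukopenia(self, sirs_table):
        # daytime extremes of the injured course: HR and WBC criteria met,
        # RR and temperature within their bands -> SIRS state
        snap = make_snapshot(phase="day", hr=201.0, rr=20.0, temp=39.2, wbc=3.9)
        res = evaluate_sirs(snap, sirs_table)
        assert res.criteria == {"hr": True, "rr": False, "temp": False, "wbc": True}
        assert res.n_met == 2 and res.sirs_state and res.complete

    def test_phase_means_meet_nothing(self, sirs_table):
        for phase in ("day", "night"):
            res = evaluate_sirs(make_snapshot(phase=phase), sirs_table)
            assert res.n_met == 0 and not res.sirs_state

    def test_thresholds_are_strict(self, sirs_table):
        at_upper = make_snapshot(phase="day", hr=130.0)
        above = make_snapshot(phase="day", hr=130.5)
        assert not evaluate_sirs(at_upper, sirs_table).criteria["hr"]
        assert evaluate_sirs(above, sirs_table).criteria["hr"]

    def test_phase_selects_threshold(self, sirs_table):
        # 120 bpm is within the day band (<=130) but above the night band (116)
        assert not evaluate_sirs(make_snapshot(phase="day", hr=120.0),
                                 sirs_table).criteria["hr"]
        assert evaluate_sirs(make_snapshot(phase="night", hr=120.0),
                             sirs_table).criteria["hr"]

    def test_missing_parameter_incomplete(self, sirs_table):
        res = evaluate_sirs(make_snapshot(wbc=None, hr=201.0), sirs_table)
        assert res.criteria["wbc"] is None
        assert res.n_met == 1 and not res.complete


SOFA_EDGES = [
    # (system, value, expected)
    ("respiratory", 418.15, 0), ("respiratory", 400.0, 0),
    ("respiratory", 399.9, 1), ("respiratory", 300.0, 1),
    ("respiratory", 299.9, 2), ("respiratory", 200.0, 2),
    ("respiratory", 199.9, 3), ("respiratory", 100.0, 3),
    ("respiratory", 99.9, 4),
    ("renal", 0.3, 0), ("renal", 1.4, 0), ("renal", 1.44, 0),
    ("renal", 1.45, 1), ("renal", 2.0, 1), ("renal", 2.4, 1),
    ("renal", 2.5, 2), ("renal", 3.4, 2), ("renal", 3.5, 3),
    ("renal", 4.9, 3), ("renal", 5.0, 4), ("renal", 0.2, 0),
    ("hepatic", 0.53, 0), ("hepatic", 0.6, 0), ("hepatic", 0.65, 1),
    ("hepatic", 2.0, 1), ("hepatic", 2.1, 2), ("hepatic", 5.0, 2),
    ("hepatic", 5.1, 3), ("hepatic", 10.0, 3), ("hepatic", 10.1, 4),
    ("hepatic", 0.11, 0),
    ("hematological", 132.2, 1), ("hematological", 151.0, 0),
    ("hematological", 150.0, 1), ("hematological", 100.0, 2),
    ("hematological", 100.5, 1), ("hematological", 50.0, 3),
    ("hematological", 20.0, 4), ("hematological", 20.5, 3),
    ("cardiovascular", 100.0, 0), ("cardiovascular", 71.0, 0),
    ("cardiovascular", 70.0, 1), ("cardiovascular", 60.0, 1),
    ("cardiovascular", 59.0, 2), ("cardiovascular", 50.0, 2),
    ("cardiovascular", 49.0, 3), ("cardiovascular", 40.0, 3),
    ("cardiovascular", 39.0, 4),
    ("neurological", 11.0, 0), ("neurological", 10.0, 0),
    ("neurological", 9.9, 1), ("neurological", 8.0, 1),
    ("neurological", 7.9, 2), ("neurological", 6.6, 2), ("neurological", 6.0, 2),
    ("neurological", 5.9, 3), ("neurological", 4.0, 3),
    ("neurological", 3.9, 4), ("neurological", 2.0, 4),
]


class TestSofa:
    @pytest.mark.parametrize("system, value, expected", SOFA_EDGES)
    def test_band_edges(self, system, value, expected):
        assert sofa_component(system, value) == expected

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError):
            sofa_component("cardiac", 1.0)

    def test_injured_extrema_composite(self):
        # thrombocytopenia (132.2) and creatinine peak (2.0) each score 1;
        # P/F 418.15, bilirubin 0.53, MAP 100 and SNORT 11 score 0
        snap = make_snapshot(pf_ratio=418.15, creatinine=2.0, bilirubin=0.53,
                             platelets=132.2, map=100.0, snort=11.0)
        res = sofa_total(snap, baseline_total=0)
        assert res.components == {"respiratory": 0, "renal": 1, "hepatic": 0,
                                  "hematological": 1, "cardiovascular": 0,
                                  "neurological": 0}
        assert res.total == 2 and res.sepsis_flag is True

    def test_all_normal(self):
        res = sofa_total(make_snapshot(), baseline_total=0)
        assert res.total == 0 and res.sepsis_flag is False

    def test_below_table_value_noted(self):
        res = sofa_total(make_snapshot(bilirubin=0.11), baseline_total=0)
        assert res.components["hepatic"] == 0
        assert any("bilirubin" in n for n in res.notes)

    def test_missing_component_partial(self):
        res = sofa_total(make_snapshot(pf_ratio=None), baseline_total=0)
        assert res.components["respiratory"] is None
        assert not res.complete and res.sepsis_flag is None
        # ... unless the partial total already clears baseline + 2
        res2 = sofa_total(make_snapshot(pf_ratio=None, snort=5.0), baseline_total=0)
        assert res2.sepsis_flag is True

    def test_baseline_shift_controls_flag(self):
        snap = make_snapshot(platelets=132.2, creatinine=2.0)
        assert sofa_total(snap, baseline_total=0).sepsis_flag is True
        assert sofa_total(snap, baseline_total=1).sepsis_flag is False


class TestNews2:
    def test_phase_mean_is_zero_points(self, news2_bands):
        assert news2_points("hr", 92.0, "night", news2_bands) == (0, False)

    def test_peak_tachycardia_extreme(self, news2_bands):
        assert news2_points("hr", 201.0, "day", news2_bands) == (3, True)

    def test_depressed_snort_extreme(self, news2_bands):
        assert news2_points("snort", 6.6, "day", news2_bands) == (3, True)
        assert news2_points("snort", 10.0, "day", news2_bands) == (0, False)

    @pytest.mark.parametrize("value, expected", [
        (98.0, (0, False)), (96.0, (0, False)), (95.0, (1, False)),
        (94.0, (1, False)), (93.0, (2, False)), (92.0, (2, False)),
        (91.0, (3, True)), (85.0, (3, True)),
    ])
    def test_spo2_fixed_bands(self, news2_bands, value, expected):
        assert news2_points("spo2", value, "day", news2_bands) == expected

    @pytest.mark.parametrize("value, expected_pts, expected_extreme", [
        # derived day bands: 0-band 85-115, thresholds 130/145/160 up,
        # 70/55/40 down; the 1-SD..2-SD gap scores 0
        (115.0, 0, False), (116.0, 0, False), (129.9, 0, False),
        (130.0, 1, False), (144.9, 1, False), (145.0, 2, False),
        (159.9, 2, False), (160.0, 3, True),
        (85.0, 0, False), (84.0, 0, False), (70.5, 0, False),
        (70.0, 1, False), (55.5, 1, False), (55.0, 2, False),
        (40.5, 2, False), (40.0, 3, True),
    ])
    def test_derived_band_edges_both_sides(self, news2_bands, value,
                                           expected_pts, expected_extreme):
        assert news2_points("hr", value, "day", news2_bands) == \
            (expected_pts, expected_extreme)

    def test_unknown_parameter_rejected(self, news2_bands):
        with pytest.raises(KeyError):
            news2_points("lactate", 2.0, "day", news2_bands)

    def test_total_at_phase_means(self, news2_bands):
        res = news2_total(make_snapshot(), news2_bands)
        assert res.total == 0 and not res.positive

    def test_single_extreme_is_positive(self, news2_bands):
        res = news2_total(make_snapshot(snort=6.0), news2_bands)
        assert res.total == 3 and res.extreme_flag and res.positive

    def test_sum_rule_five_single_points(self, news2_bands):
        snap = make_snapshot(phase="day", hr=130.0, rr=30.0, sbp=113.0,
                             temp=39.9, spo2=95.0)
        res = news2_total(snap, news2_bands)
        assert res.total == 5 and not res.extreme_flag and res.positive

    def test_four_points_not_positive(self, news2_bands):
        snap = make_snapshot(phase="day", hr=130.0, rr=30.0, sbp=113.0, temp=39.9)
        res = news2_total(snap, news2_bands)
        assert res.total == 4 and not res.positive

    def test_missing_parameters_score_zero_and_are_listed(self, news2_bands):
        res = news2_total(make_snapshot(spo2=None, sbp=None), news2_bands)
        assert res.missing == ("spo2", "sbp")
        assert res.points["spo2"] == 0 and res.points["sbp"] == 0

    def test_all_missing_rejected(self, news2_bands):
        empty = VitalsSnapshot(animal_id="x", time_h=0.0, phase="day")
        with pytest.raises(ValueError):
            news2_total(empty, news2_bands)


class TestSnortRubric:
    def test_all_max_is_eleven(self):
        maxima = [mx for _, _, mx in DEFAULT_SNORT_RUBRIC.items]
        assert snort_score(maxima) == 11

    def test_all_min_is_two(self):
        minima = [mn for _, mn, _ in DEFAULT_SNORT_RUBRIC.items]
        assert snort_score(minima) == 2

    def test_includes_food_response_item(self):
        names = [name for name, _, _ in DEFAULT_SNORT_RUBRIC.items]
        assert "response_to_offered_food_and_treat" in names

    def test_out_of_range_subscore_rejected(self):
        values = [mx for _, _, mx in DEFAULT_SNORT_RUBRIC.items]
        values[0] += 1
        with pytest.raises(ValueError):
            snort_score(values)

    def test_bad_rubric_rejected(self):
        with pytest.raises(ValueError):
            SnortRubric(items=(("a", 0, 20),))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_bruteforce_sum(self, data):
        values = [data.draw(st.integers(mn, mx), label=name)
                  for name, mn, mx in DEFAULT_SNORT_RUBRIC.items]
        assert snort_score(values) == int(np.clip(sum(values), 2, 11))


class TestPurityAndMonotonicity:
    def test_scoring_is_pure(self, sirs_table, news2_bands):
        snap = make_snapshot(hr=150.0, wbc=5.0, snort=7.0)
        for _ in range(3):
            assert evaluate_sirs(snap, sirs_table) == evaluate_sirs(snap, sirs_table)
            assert news2_total(snap, news2_bands) == news2_total(snap, news2_bands)
            assert sofa_total(snap, 0) == sofa_total(snap, 0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(hr=st.floats(35, 250), bump=st.floats(0, 60))
    def test_worsening_hr_never_lowers_scores(self, sirs_table, news2_bands,
                                              hr, bump):
        worse_hr = hr + bump if hr >= 100.0 else max(hr - bump, 31.0)
        a = make_snapshot(phase="day", hr=hr)
        b = make_snapshot(phase="day", hr=worse_hr)
        assert news2_total(b, news2_bands).total >= news2_total(a, news2_bands).total
        assert evaluate_sirs(b, sirs_table).n_met >= evaluate_sirs(a, sirs_table).n_met

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(platelets=st.floats(6, 500), drop=st.floats(0, 100))
    def test_falling_platelets_never_lower_sofa(self, platelets, drop):
        worse = max(platelets - drop, 5.0)
        a = sofa_total(make_snapshot(platelets=platelets), 0)
        b = sofa_total(make_snapshot(platelets=worse), 0)
        assert b.total >= a.total

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.data())
    def test_score_ranges_always_hold(self, sirs_table, news2_bands, data):
        snap = make_snapshot(
            phase=data.draw(st.sampled_from(["day", "night"])),
            hr=data.draw(st.floats(31, 300)),
            rr=data.draw(st.floats(1, 80)),
            temp=data.draw(st.floats(33, 43)),
            wbc=data.draw(st.floats(0.2, 60)),
            platelets=data.draw(st.floats(6, 700)),
            creatinine=data.draw(st.floats(0.1, 12)),
            bilirubin=data.draw(st.floats(0.02, 15)),
            map=data.draw(st.floats(21, 160)),
            pf_ratio=data.draw(st.floats(40, 600)),
            snort=data.draw(st.floats(2, 11)),
            spo2=data.draw(st.floats(60, 100)),
            sbp=data.draw(st.floats(41, 260)))
        sirs = evaluate_sirs(snap, sirs_table)
        assert 0 <= sirs.n_met <= 4
        sofa = sofa_total(snap, 0)
        assert 0 <= sofa.total <= 24
        assert all(0 <= v <= 4 for v in sofa.components.values())
        news2 = news2_total(snap, news2_bands)
        assert all(0 <= v <= 3 for v in news2.points.values())
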