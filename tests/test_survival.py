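"""Record assembly rules and Kaplan-Meier estimation against hand oracles."""

import datetime as dt
import math

import numpy as np
import pytest

from rwpfs import (
    CensorType,
    EventSource,
    EventType,
    LineAdvancementEvent,
    ProgressionCapture,
    SurvivalRecord,
    assemble_rwos_record,
    assemble_rwpfs_record,
    event_breakdown,
    km_fit,
    log_rank,
    median_survival,
    run_pipeline,
    stratified_rwpfs,
)
from rwpfs.ehr import NoteType
from rwpfs.simulate import SimulationConfig, simulate_cohort

D = dt.date
INDEX = D(2016, 1, 1)
END = D(2021, 12, 31)


def cap(days, note_type=NoteType.clinical_document, pid="P1"):
    day = INDEX + dt.timedelta(days)
    return ProgressionCapture(
        patient_id=pid, capture_date=day, note_id=f"n{days}",
        note_type=note_type, sentence="Disease progression.",
        normalized_sentence="disease progression")


def adv(days, pid="P1"):
    return LineAdvancementEvent(patient_id=pid, drug_name="capecitabine",
                                advancement_date=INDEX + dt.timedelta(days))


def rec(months, event, pid="R", censor=CensorType.last_encounter):
    return SurvivalRecord(
        patient_id=pid, index_date=INDEX, duration_months=months, event=event,
        event_type=EventType.nlp_progression if event else EventType.none,
        event_source=EventSource.clinical_document if event else EventSource.none,
        censor_type=CensorType.none if event else censor)


class TestRwpfsAssembly:
    def test_thirty_day_exclusion_drops_only_early_captures(self):
        r = assemble_rwpfs_record("P1", INDEX, [cap(19), cap(200)], None,
                                  None, INDEX + dt.timedelta(400), END)
        assert r.event and r.event_type is EventType.nlp_progression
        assert r.duration_months == pytest.approx(200 / 30.4375)  # 6.57 months

    def test_no_event_censors_at_death(self):
        r = assemble_rwpfs_record("P1", INDEX, [], None,
                                  INDEX + dt.timedelta(300),
                                  INDEX + dt.timedelta(300), END)
        assert not r.event and r.censor_type is CensorType.death
        assert r.duration_months == pytest.approx(300 / 30.4375)  # 9.86 months

    def test_earlier_advancement_beats_later_capture(self):
        r = assemble_rwpfs_record("P1", INDEX, [cap(400)], adv(250),
                                  None, INDEX + dt.timedelta(500), END)
        assert r.event_type is EventType.line_advancement
        assert r.event_source is EventSource.structured
        assert r.duration_months == pytest.approx(250 / 30.4375)

    def test_same_day_progression_wins_over_advancement(self):
        r = assemble_rwpfs_record("P1", INDEX, [cap(250)], adv(250),
                                  None, INDEX + dt.timedelta(500), END)
        assert r.event_type is EventType.nlp_progression

    def test_event_on_censor_date_counts_as_event(self):
        r = assemble_rwpfs_record("P1", INDEX, [cap(100)], None,
                                  None, INDEX + dt.timedelta(100), END)
        assert r.event

    def test_event_after_censor_becomes_censored(self):
        r = assemble_rwpfs_record("P1", INDEX, [cap(400)], None,
                                  None, INDEX + dt.timedelta(300), END)
        assert not r.event and r.censor_type is CensorType.last_encounter

    def test_exactly_thirty_days_is_excluded(self):
        r = assemble_rwpfs_record("P1", INDEX, [cap(30)], None,
                                  None, INDEX + dt.timedelta(300), END)
        assert not r.event

    def test_nothing_to_censor_on_is_an_error(self):
        with pytest.raises(ValueError, match="censor"):
            assemble_rwpfs_record("P1", INDEX, [], None, None, None, None)


class TestRwosAssembly:
    def test_death_is_the_event(self):
        r = assemble_rwos_record("P1", INDEX, INDEX + dt.timedelta(600),
                                 INDEX + dt.timedelta(580), END)
        assert r.event and r.event_type is EventType.death_event
        assert r.duration_months == pytest.approx(600 / 30.4375)  # 19.71

    def test_alive_censors_at_last_encounter(self):
        r = assemble_rwos_record("P1", INDEX, None,
                                 INDEX + dt.timedelta(500), END)
        assert not r.event and r.censor_type is CensorType.last_encounter
        assert r.duration_months == pytest.approx(500 / 30.4375)  # 16.43

    def test_death_after_study_end_censors_at_study_end(self):
        r = assemble_rwos_record("P1", INDEX, END + dt.timedelta(30),
                                 END + dt.timedelta(40), END)
        assert not r.event and r.censor_type is CensorType.end_of_study


class TestKaplanMeier:
    def test_hand_product_limit(self):
        records = [rec(5, True), rec(10, True), rec(15, False)]
        curve = km_fit(records)
        assert curve.event_times == [5.0, 10.0]
        assert curve.survival == pytest.approx([2 / 3, 1 / 3])
        assert curve.at_risk == [3, 2]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_fit([rec(m, False) for m in (3, 6, 9)])
        assert curve.event_times == []
        assert median_survival(curve).median_months is None  # not reached

    def test_single_event_drops_to_zero(self):
        curve = km_fit([rec(7, True)])
        assert curve.survival == pytest.approx([0.0])
        assert median_survival(curve).median_months == 7.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_fit([])

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            months = np.round(rng.exponential(20.0, size=12), 3)
            records = [rec(m, True, pid=f"R{i}") for i, m in enumerate(months)]
            curve = km_fit(records)
            for t, s in zip(curve.event_times, curve.survival):
                assert s == pytest.approx((months > t).mean())

    def test_greenwood_variance_matches_hand_formula(self):
        curve = km_fit([rec(5, True), rec(10, True), rec(15, False)])
        # at t=5: S=2/3, var = S^2 * (1/(3*2)) ; at t=10 add 1/(2*1)
        assert curve.variance[0] == pytest.approx((2 / 3) ** 2 * (1 / 6))
        assert curve.variance[1] == pytest.approx((1 / 3) ** 2 * (1 / 6 + 1 / 2))


class TestMedian:
    def test_median_is_first_time_survival_reaches_half(self):
        est = median_survival(km_fit([rec(5, True), rec(10, True), rec(15, False)]))
        assert est.median_months == 10.0

    def test_exact_half_counts(self):
        est = median_survival(km_fit([rec(5, True), rec(9, False)]))
        assert est.median_months == 5.0

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(7)
        months = rng.exponential(20.0, size=80)
        events = rng.random(80) < 0.7
        records = [rec(float(m), bool(e), pid=f"R{i}")
                   for i, (m, e) in enumerate(zip(months, events))]
        est = median_survival(km_fit(records))
        assert est.ci_low <= est.median_months <= est.ci_high

    def test_median_ci_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import median_survival_times

        rng = np.random.default_rng(11)
        months = rng.exponential(20.0, size=120)
        events = rng.random(120) < 0.65
        records = [rec(float(m), bool(e), pid=f"R{i}")
                   for i, (m, e) in enumerate(zip(months, events))]
        est = median_survival(km_fit(records))
        kmf = KaplanMeierFitter().fit(months, events)
        assert est.median_months == pytest.approx(float(kmf.median_survival_time_))
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        assert est.ci_low == pytest.approx(lo)
        if math.isinf(hi):
            assert est.ci_high is None
        else:
            assert est.ci_high == pytest.approx(hi)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        group = [rec(m, True, pid=f"R{m}") for m in (3, 6, 9, 12)]
        result = log_rank(group, group)
        assert result.statistic == pytest.approx(0.0, abs=1e-9)
        assert result.p_value == pytest.approx(1.0)

    def test_doubled_durations_detected(self):
        rng = np.random.default_rng(5)
        months = rng.exponential(10.0, size=200)
        a = [rec(float(m), True, pid=f"A{i}") for i, m in enumerate(months)]
        b = [rec(float(2 * m), True, pid=f"B{i}") for i, m in enumerate(months)]
        assert log_rank(a, b).p_value < 0.05

    def test_symmetric_in_group_order(self):
        a = [rec(m, True) for m in (2.0, 4.0, 8.0)]
        b = [rec(m, True) for m in (3.0, 9.0, 27.0)]
        assert log_rank(a, b).statistic == pytest.approx(log_rank(b, a).statistic)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank([], [rec(1.0, True)])


class TestCohortLevel:
    def test_breakdown_sums_to_cohort_size(self, sim316, config):
        bundle, _ = sim316
        result = run_pipeline(bundle, config)
        breakdown = event_breakdown(result.records)
        assert sum(breakdown.values()) == len(result.records)

    def test_pooled_equals_clinical_only_without_radiology(self, config):
        bundle, _ = simulate_cohort(SimulationConfig(
            n_patients=30, seed=21, radiology_coverage=0.0))
        result = run_pipeline(bundle, config)
        _, _, pooled = stratified_rwpfs(
            bundle, result.members, result.captures, result_therapy(), "pooled")
        _, _, clinical = stratified_rwpfs(
            bundle, result.members, result.captures, result_therapy(), "clinical_only")
        assert pooled == clinical

    def test_radiology_lag_raises_radiology_only_median(self, config):
        bundle, _ = simulate_cohort(SimulationConfig(
            n_patients=120, seed=13, radiology_coverage=1.0,
            radiology_lag_days=60, doc_delay_probability=0.0))
        result = run_pipeline(bundle, config)
        _, _, pooled = stratified_rwpfs(
            bundle, result.members, result.captures, result_therapy(), "pooled")
        _, _, radiology = stratified_rwpfs(
            bundle, result.members, result.captures, result_therapy(),
            "radiology_only")
        assert radiology.median_months >= pooled.median_months

    def test_unknown_source_filter_rejected(self, sim_small, config):
        bundle, _ = sim_small
        result = run_pipeline(bundle, config)
        with pytest.raises(ValueError):
            stratified_rwpfs(bundle, result.members, result.captures,
                             result_therapy(), "everything")


def result_therapy():
    from rwpfs import TherapyConfig

    return TherapyConfig()


class TestSubgroups:
    def test_partition_sizes_sum_to_n(self, sim316, config):
        from rwpfs import subgroup_rwpfs

        bundle, _ = sim316
        result = run_pipeline(bundle, config)
        flags = {m.patient_id: (m.prior_systemic, m.concomitant_systemic)
                 for m in result.members}
        groups = subgroup_rwpfs(result.records, flags)
        assert sum(len(g.records) for g in groups.values()) == len(result.records)

    def test_all_false_flags_reproduce_full_cohort(self):
        records = [rec(m, True, pid=f"R{i}") for i, m in enumerate((5.0, 10.0))]
        from rwpfs import subgroup_rwpfs

        groups = subgroup_rwpfs(records, {r.patient_id: (False, False)
                                          for r in records})
        assert len(groups[(False, False)].records) == 2
        assert groups[(True, True)].median is None
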