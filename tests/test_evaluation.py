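"""Temporal confusion matrix, metric recovery, ablations, sensitivity."""

import datetime as dt
from fractions import Fraction

import numpy as np
import pytest

from rwpfs import (
    AblationPoint,
    AttritionCriteria,
    CensorType,
    ConfusionCounts,
    Outcome,
    SimulationConfig,
    TherapyConfig,
    apply_attrition,
    classify_patient,
    compute_metrics,
    km_fit,
    median_survival,
    recover_confusion_matrices,
    remove_event_rows,
    run_ablation,
    sensitivity_death_handling,
    sensitivity_missingness,
    simulate_cohort,
)
from rwpfs.evaluation import round_half_up

from test_survival import rec

D = dt.date


class TestClassifyPatient:
    BASE = D(2016, 1, 1)

    def day(self, n):
        return self.BASE + dt.timedelta(n)

    @pytest.mark.parametrize("auto,manual,expected", [
        (100, 110, Outcome.TP),    # within the +/-30 day window
        (40, 100, Outcome.FP),     # captured >30 days early
        (200, 100, Outcome.FN),    # captured >30 days late
        (None, None, Outcome.TN),
        (100, None, Outcome.FP),
        (None, 100, Outcome.FN),
        (130, 100, Outcome.TP),    # boundary: exactly 30 days late
        (131, 100, Outcome.FN),
    ])
    def test_examples(self, auto, manual, expected):
        a = self.day(auto) if auto is not None else None
        m = self.day(manual) if manual is not None else None
        assert classify_patient(a, m, 30) is expected

    def test_exhaustive_and_exclusive(self):
        offsets = [None] + list(range(0, 200, 13))
        for a in offsets:
            for m in offsets:
                out = classify_patient(
                    self.day(a) if a is not None else None,
                    self.day(m) if m is not None else None)
                assert out in set(Outcome)


class TestComputeMetrics:
    def test_closed_forms(self):
        r = compute_metrics(ConfusionCounts(tp=37, fp=5, tn=18, fn=1))
        assert r.sensitivity == pytest.approx(37 / 38)
        assert r.specificity == pytest.approx(18 / 23)
        assert r.precision == pytest.approx(37 / 42)
        assert r.accuracy == pytest.approx(55 / 61)
        assert r.f1 == pytest.approx(74 / 80)

    def test_zero_denominators_are_undefined_not_zero(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert r.accuracy == 1.0 and r.specificity == 1.0
        assert r.sensitivity is None and r.precision is None and r.f1 is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))


class TestRecovery:
    def test_half_up_rounding(self):
        assert round_half_up(Fraction(905, 10000) * 100, 1) == Fraction("9.1")
        assert round_half_up(Fraction("90.25"), 1) == Fraction("90.3")
        assert round_half_up(Fraction("90.24"), 1) == Fraction("90.2")

    def test_unique_recovery_from_three_metrics(self):
        sols = recover_confusion_matrices(
            61, {"sensitivity": 97.4, "specificity": 78.3, "precision": 88.1})
        assert sols == [ConfusionCounts(tp=37, fp=5, tn=18, fn=1)]

    def test_recovery_with_accuracy_constraint(self):
        sols = recover_confusion_matrices(
            200, {"sensitivity": 89.7, "specificity": 95.7, "accuracy": 92.5})
        assert ConfusionCounts(tp=96, fp=4, tn=89, fn=11) in sols

    def test_inconsistent_metrics_give_empty_list(self):
        assert recover_confusion_matrices(10, {"sensitivity": 99.9}) == []

    def test_self_consistency(self):
        """Every recovered matrix reproduces the rounded inputs."""
        metrics = {"sensitivity": 92.5, "specificity": 83.0, "precision": 86.0}
        sols = recover_confusion_matrices(100, metrics)
        assert sols
        for c in sols:
            assert round_half_up(Fraction(c.tp, c.tp + c.fn) * 100, 1) == Fraction("92.5")
            assert round_half_up(Fraction(c.tn, c.tn + c.fp) * 100, 1) == Fraction("83.0")
            assert round_half_up(Fraction(c.tp, c.tp + c.fp) * 100, 1) == Fraction("86.0")


def _ablation_setup(**overrides):
    cfg = dict(n_patients=80, seed=17)
    cfg.update(overrides)
    bundle, truth = simulate_cohort(SimulationConfig(**cfg))
    members, _ = apply_attrition(bundle, AttritionCriteria(), TherapyConfig())
    manual = {r.patient_id: r.true_progression_date for r in truth.records}
    return bundle, members, manual


class TestAblation:
    def test_subject_ablation_identical_without_family_sentences(self, config):
        bundle, members, manual = _ablation_setup(family_history_rate=0.0)
        full = run_ablation(bundle, members, config, TherapyConfig(), None, manual)
        ablated = run_ablation(bundle, members, config, TherapyConfig(),
                               AblationPoint.subject_model, manual)
        assert ablated.counts == full.counts
        assert ablated.median == full.median
        assert ablated.records == full.records

    def test_certainty_ablation_lowers_specificity_and_median(self, config):
        bundle, members, manual = _ablation_setup(negated_sentence_rate=0.3)
        full = run_ablation(bundle, members, config, TherapyConfig(), None, manual)
        ablated = run_ablation(bundle, members, config, TherapyConfig(),
                               AblationPoint.certainty_model, manual)
        assert ablated.metrics.specificity < full.metrics.specificity
        assert ablated.median.median_months < full.median.median_months

    def test_ablated_first_captures_never_later(self, config):
        from rwpfs import extract_progression_captures, first_capture_dates

        bundle, members, _ = _ablation_setup(
            negated_sentence_rate=0.3, past_history_rate=0.3)
        pids = [m.patient_id for m in members]
        full = first_capture_dates(
            extract_progression_captures(bundle, config), pids)
        for point, flags in (
            ("certainty", {"skip_certainty": True}),
            ("temporal", {"skip_temporality": True}),
            ("post", {"skip_postprocessing": True}),
        ):
            ablated = first_capture_dates(
                extract_progression_captures(bundle, config, **flags), pids)
            for pid in pids:
                if full[pid] is not None:
                    assert ablated[pid] is not None
                    assert ablated[pid] <= full[pid], point

    def test_all_three_is_superset_of_each_single_ablation(self, config):
        from rwpfs import extract_progression_captures

        bundle, _, _ = _ablation_setup(
            negated_sentence_rate=0.2, family_history_rate=0.2,
            past_history_rate=0.2)
        key = lambda c: (c.patient_id, c.note_id, c.normalized_sentence)
        all_three = {key(c) for c in extract_progression_captures(
            bundle, config, skip_certainty=True, skip_subject=True,
            skip_temporality=True)}
        for flags in ({"skip_certainty": True}, {"skip_subject": True},
                      {"skip_temporality": True}):
            single = {key(c) for c in extract_progression_captures(
                bundle, config, **flags)}
            assert single <= all_three

    def test_unknown_point_rejected(self, config):
        bundle, members, manual = _ablation_setup()
        with pytest.raises(ValueError):
            run_ablation(bundle, members, config, TherapyConfig(),
                         "warp_drive", manual)


class TestMissingness:
    def _records(self):
        rng = np.random.default_rng(3)
        months = rng.exponential(20.0, size=200)
        events = rng.random(200) < 0.65
        return [rec(float(m), bool(e), pid=f"R{i}")
                for i, (m, e) in enumerate(zip(months, events))]

    def test_zero_fraction_is_identity(self):
        records = self._records()
        out = sensitivity_missingness(records, fractions=(0.0,), seed=1)
        assert out[0.0][0] == median_survival(km_fit(records))

    def test_only_event_rows_are_removed(self):
        records = self._records()
        n_censored = sum(not r.event for r in records)
        n_events = sum(r.event for r in records)
        subset = remove_event_rows(records, 0.3,
                                   np.random.default_rng(0))
        assert sum(not r.event for r in subset) == n_censored
        assert sum(r.event for r in subset) == n_events - round(0.3 * n_events)

    def test_seeded_runs_are_reproducible(self):
        records = self._records()
        a = sensitivity_missingness(records, repetitions=3, seed=7)
        b = sensitivity_missingness(records, repetitions=3, seed=7)
        assert a == b

    def test_fraction_at_least_one_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_missingness(self._records(), fractions=(1.0,))


class TestDeathHandling:
    def test_no_deaths_means_identical_variants(self):
        records = [rec(m, e, pid=f"R{i}") for i, (m, e) in
                   enumerate([(5.0, True), (8.0, False), (12.0, True)])]
        censored, as_event, lr = sensitivity_death_handling(records)
        assert censored == as_event
        assert lr.statistic == pytest.approx(0.0, abs=1e-9)

    def test_event_count_bookkeeping(self, sim316, config):
        from rwpfs import run_pipeline

        bundle, _ = sim316
        records = run_pipeline(bundle, config).records
        censored, as_event, _ = sensitivity_death_handling(records)
        n_death_censors = sum(
            1 for r in censored
            if not r.event and r.censor_type is CensorType.death)
        assert sum(r.event for r in as_event) == (
            sum(r.event for r in censored) + n_death_censors)

    def test_death_as_event_median_is_never_larger(self, sim316, config):
        from rwpfs import run_pipeline

        bundle, _ = sim316
        records = run_pipeline(bundle, config).records
        censored, as_event, _ = sensitivity_death_handling(records)
        m_censor = median_survival(km_fit(censored)).median_months
        m_event = median_survival(km_fit(as_event)).median_months
        assert m_event <= m_censor
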