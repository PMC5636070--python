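"""Cohort statistics: stratification, group tests, longitudinal change."""

import numpy as np
import pandas as pd
import pytest

from stridekit.cohort import (
    DegenerateDataError,
    PairingError,
    ReportError,
    StratificationError,
    build_report,
    cohort_table,
    compare_groups,
    longitudinal_change,
    stratify_subjects,
)
from stridekit.io import SubjectRecord
from stridekit.parameters import WalkSummary


def _table(rows):
    return pd.DataFrame(rows)


class TestStratification:
    @pytest.mark.parametrize(
        "updrs,band",
        [(1, "low"), (12, "low"), (13, "middle"), (22, "middle"), (23, "high"), (40, "high")],
    )
    def test_updrs_band_boundaries(self, updrs, band):
        table = _table([
            dict(subject_id="P1", group="PD", updrs_iii_total=updrs),
        ])
        out = stratify_subjects(table, "updrs_band")
        assert out["stratum"].iloc[0] == band

    def test_controls_form_their_own_stratum(self):
        table = _table([
            dict(subject_id="C1", group="control", hoehn_yahr=None),
            dict(subject_id="P1", group="PD", hoehn_yahr=2),
        ])
        out = stratify_subjects(table, "hoehn_yahr")
        assert list(out["stratum"]) == ["control", "hoehn_yahr_2"]

    def test_missing_field_on_pd_row(self):
        table = _table([dict(subject_id="P1", group="PD", hoehn_yahr=np.nan)])
        with pytest.raises(StratificationError):
            stratify_subjects(table, "hoehn_yahr")

    @pytest.mark.parametrize("scheme", ["group", "hoehn_yahr", "updrs_band", "gait_item"])
    def test_partition_property(self, scheme):
        rng = np.random.default_rng(0)
        rows = [
            dict(
                subject_id=f"P{i}", group="PD",
                hoehn_yahr=int(rng.integers(1, 4)),
                updrs_iii_total=int(rng.integers(1, 50)),
                gait_item=int(rng.integers(0, 3)),
            )
            for i in range(20)
        ] + [dict(subject_id=f"C{i}", group="control") for i in range(10)]
        out = stratify_subjects(_table(rows), scheme)
        # every subject in exactly one stratum
        assert out["stratum"].notna().all()
        assert len(out) == 30

    def test_unknown_scheme(self):
        with pytest.raises(StratificationError):
            stratify_subjects(_table([dict(subject_id="x", group="PD")]), "age_band")


class TestCompareGroups:
    def test_identical_samples_null_result(self):
        res = compare_groups({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_equal_group_means_give_zero_f(self):
        res = compare_groups({"a": [1, 2, 3], "b": [2, 1, 3], "c": [3, 2, 1]})
        assert res.test == "anova"
        assert res.statistic == pytest.approx(0.0)

    def test_textbook_t_against_closed_form(self):
        a = np.array([1, 2, 3, 4, 5], float)
        b = np.array([2, 3, 4, 5, 6], float)
        res = compare_groups({"a": a, "b": b})
        # pooled-variance Student t, computed independently
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t_expected == pytest.approx(-1.0)
        assert res.statistic == pytest.approx(t_expected, abs=1e-12)

    def test_bonferroni_capped_and_monotone(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        res = compare_groups(groups)
        n_pairs = 3
        raws = sorted(v["p_raw"] for v in res.pairwise.values())
        adjs = sorted(v["p_adjusted"] for v in res.pairwise.values())
        for praw, padj in zip(raws, adjs):
            assert padj == pytest.approx(min(1.0, praw * n_pairs))
            assert padj >= praw
        assert adjs == sorted(adjs)

    def test_degenerate_data(self):
        with pytest.raises(DegenerateDataError):
            compare_groups({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})

    def test_type_i_error_calibration(self):
        # 1000 seeded null replicates at n = 30 per group: the t-test
        # rejects at the nominal 5 % rate (99 % binomial band)
        rng = np.random.default_rng(12345)
        from scipy import stats

        a = rng.normal(0, 1, (1000, 30))
        b = rng.normal(0, 1, (1000, 30))
        _, p = stats.ttest_ind(a, b, axis=1)
        rate = float(np.mean(p < 0.05))
        band = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < band


class TestLongitudinalChange:
    def _row(self, gait=1, length=1.0, date="2012-01-01"):
        return dict(subject_id="P1", gait_item=gait, stride_length=length,
                    visit_date=date)

    def test_stable_when_rating_unchanged(self):
        rec = longitudinal_change(self._row(1), self._row(1, 1.01, "2013-01-01"),
                                  parameters=["stride_length"])
        assert rec.gait_class == "stable"

    def test_percent_change_arithmetic(self):
        rec = longitudinal_change(self._row(1, 1.00), self._row(1, 1.044, "2013-01-01"),
                                  parameters=["stride_length"])
        assert rec.percent_change["stride_length"] == pytest.approx(4.4)

    def test_improved_is_lower_rating(self):
        rec = longitudinal_change(self._row(2, 1.00), self._row(1, 1.05, "2013-01-01"),
                                  parameters=["stride_length"])
        assert rec.gait_class == "improved"
        assert rec.percent_change["stride_length"] == pytest.approx(5.0)

    def test_worsened_is_higher_rating(self):
        rec = longitudinal_change(self._row(0), self._row(2, 0.9, "2013-01-01"),
                                  parameters=["stride_length"])
        assert rec.gait_class == "worsened"

    def test_months_between_visits(self):
        rec = longitudinal_change(self._row(1, date="2012-01-01"),
                                  self._row(1, date="2013-01-01"),
                                  parameters=["stride_length"])
        assert rec.months_between == pytest.approx(12.0, abs=0.1)

    def test_subject_mismatch(self):
        other = dict(subject_id="P2", gait_item=1, stride_length=1.0)
        with pytest.raises(PairingError):
            longitudinal_change(self._row(), other)


class TestReport:
    def _cohort_frame(self, n=50, seed=0, effect=True):
        # subject-level values drawn from the reference group distributions
        from stridekit.synth import (
            control_reference_distribution,
            pd_reference_distribution,
        )

        rng = np.random.default_rng(seed)
        rows = []
        for group, dist in (("PD", pd_reference_distribution()),
                            ("control", control_reference_distribution())):
            for i, s in enumerate(dist.sample(rng, n)):
                rows.append(dict(
                    subject_id=f"{group}{i}", group=group,
                    stride_length=s.stride_length, stride_time=s.stride_time,
                    gait_velocity=s.stride_length / s.stride_time,
                    cadence=60 / s.stride_time,
                    stance_time_pct=100 * s.stance_fraction,
                    swing_time_pct=100 * (1 - s.stance_fraction),
                    clearance=100 * s.max_clearance,
                    hs_angle=s.hs_angle, to_angle=s.to_angle,
                    normalized_stride_length=s.stride_length / 1.71,
                ))
        return pd.DataFrame(rows)

    def test_report_has_ten_parameter_rows(self):
        report = build_report(self._cohort_frame(n=10), schemes=["group"])
        assert len(report.tables["group"]) == 10

    def test_configured_clearance_effect_is_detected(self):
        report = build_report(self._cohort_frame(n=50, seed=3), schemes=["group"])
        res = report.comparisons["group"]["clearance"]
        assert res.p_value < 0.05

    def test_degenerate_cohort_has_no_significance(self):
        rows = []
        for group in ("PD", "control"):
            for i in range(2):
                rows.append(dict(subject_id=f"{group}{i}", group=group,
                                 stride_length=1.2, stride_time=1.0))
        report = build_report(pd.DataFrame(rows), schemes=["group"])
        table = report.tables["group"]
        assert "*" not in table.to_string()
        assert "± 0.00" in table.to_string()

    def test_empty_cohort(self):
        with pytest.raises(ReportError):
            build_report(pd.DataFrame(), schemes=["group"])

    def test_cohort_table_join(self):
        subjects = [
            SubjectRecord("P1", "PD", hoehn_yahr=2, updrs_iii_total=15, gait_item=1),
            SubjectRecord("C1", "control"),
        ]
        summaries = {
            "P1": WalkSummary(means={"stride_length": 1.1}, cvs={"stride_length": 3.0},
                              n_strides=30),
            "C1": WalkSummary(means={"stride_length": 1.25}, cvs={"stride_length": 2.0},
                              n_strides=28),
        }
        df = cohort_table(subjects, summaries)
        assert len(df) == 2
        assert set(["stride_length", "cv_stride_length", "n_strides"]) <= set(df.columns)
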