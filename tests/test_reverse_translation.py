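"""Exclusion filtering, monotone-map inversion, and cohort summarization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benzrisk import (
    ChildRecord,
    CohortSchemaError,
    EmptyCohortError,
    SaturationError,
    cohort_estimate,
    filter_cohort,
    fixture_cohort_41,
    invert_air_concentration,
    read_cohort_csv,
    ttma_saturation_bound,
    ttma_urine_forward,
    write_cohort_csv,
)


def make_child(i, ttma, below_loq=False, acr_normal=True, creatinine=1.0):
    return ChildRecord(
        child_id=f"T{i:02d}",
        age=8.0,
        weight=27.0,
        height=128.0,
        ttma=ttma,
        urinary_creatinine=creatinine,
        albumin_creatinine_ratio=10.0 if acr_normal else 50.0,
        acr_normal=acr_normal,
        below_loq=below_loq,
    )


class TestFilterCohort:
    def test_fixture_counts_match_study(self):
        report = filter_cohort(fixture_cohort_41())
        assert (report.n_input, report.n_below_loq, report.n_abnormal_acr, report.n_retained) == (
            41,
            23,
            3,
            15,
        )

    def test_empty_cohort(self):
        report = filter_cohort([])
        assert report.n_input == report.n_retained == 0
        assert report.n_below_loq == report.n_abnormal_acr == 0

    def test_all_clean_records_retained(self):
        records = [make_child(i, 0.5) for i in range(5)]
        assert filter_cohort(records).n_retained == 5

    def test_record_failing_both_rules_counts_as_censored(self):
        rec = make_child(0, 0.01, below_loq=True, acr_normal=False)
        report = filter_cohort([rec])
        assert report.n_below_loq == 1 and report.n_abnormal_acr == 0

    def test_duplicate_id_rejected(self):
        rec = make_child(1, 0.5)
        with pytest.raises(CohortSchemaError):
            filter_cohort([rec, rec])

    @given(
        flags=st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=40
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_partition_input(self, flags):
        records = [
            make_child(i, 0.01 if below else 0.5, below_loq=below, acr_normal=acr_ok)
            for i, (below, acr_ok) in enumerate(flags)
        ]
        report = filter_cohort(records)
        assert (
            report.n_below_loq + report.n_abnormal_acr + report.n_retained
            == report.n_input
            == len(records)
        )
        assert {r for _, r in report.excluded} <= {"below_loq", "abnormal_acr"}


class TestInversion:
    @pytest.mark.parametrize("c_true", [0.5, 5.85, 50.0])
    def test_round_trip_air_to_air(self, c_true, params, phys):
        ttma = ttma_urine_forward(c_true, params, phys).ttma_conc
        assert invert_air_concentration(ttma, params, phys) == pytest.approx(
            c_true, rel=1e-6
        )

    @pytest.mark.parametrize("y", [0.1, 0.81, 2.0])
    def test_round_trip_ttma_to_ttma(self, y, params, phys):
        c = invert_air_concentration(y, params, phys)
        assert ttma_urine_forward(c, params, phys).ttma_conc == pytest.approx(
            y, rel=1e-6
        )

    def test_zero_maps_to_zero(self, params, phys):
        assert invert_air_concentration(0.0, params, phys) == 0.0

    def test_observation_above_ceiling_raises(self, params, phys):
        bound = ttma_saturation_bound(params, phys)
        with pytest.raises(SaturationError):
            invert_air_concentration(1.01 * bound, params, phys)

    def test_mass_balance_mode_round_trip(self, params, phys):
        ttma = ttma_urine_forward(5.85, params, phys, arterial_mode="mass_balance").ttma_conc
        rec = invert_air_concentration(ttma, params, phys, arterial_mode="mass_balance")
        assert rec == pytest.approx(5.85, rel=1e-6)


class TestCohortEstimate:
    def test_fixture_moments_match_study(self, params, phys):
        report = filter_cohort(fixture_cohort_41())
        est = cohort_estimate(report, params, phys)
        assert est.n == 15
        assert est.ttma_mean == pytest.approx(0.81, abs=0.005)
        assert est.ttma_sd == pytest.approx(0.83, abs=0.005)
        assert len(est.air_conc_per_child) == 15
        assert est.air_conc_sd > 0

    def test_single_child(self, params, phys):
        report = filter_cohort([make_child(0, 0.81)])
        est = cohort_estimate(report, params, phys)
        assert est.ttma_mean == pytest.approx(0.81)
        assert est.ttma_sd == 0.0
        assert est.air_conc_sd == 0.0

    def test_identical_children_zero_spread(self, params, phys):
        report = filter_cohort([make_child(i, 0.81) for i in range(4)])
        est = cohort_estimate(report, params, phys)
        assert est.ttma_sd == pytest.approx(0.0, abs=1e-12)
        assert est.air_conc_sd == pytest.approx(0.0, abs=1e-9)

    def test_empty_retained_raises(self, params, phys):
        report = filter_cohort([make_child(0, 0.01, below_loq=True)])
        with pytest.raises(EmptyCohortError):
            cohort_estimate(report, params, phys)

    def test_raising_one_ttma_never_decreases_mean(self, params, phys):
        records = [make_child(i, t) for i, t in enumerate([0.3, 0.8, 1.5])]
        base = cohort_estimate(filter_cohort(records), params, phys).air_conc_mean
        bumped = [make_child(i, t) for i, t in enumerate([0.3, 1.2, 1.5])]
        higher = cohort_estimate(filter_cohort(bumped), params, phys).air_conc_mean
        assert higher >= base

    def test_pooled_mode_inverts_cohort_mean(self, params, phys):
        records = [make_child(i, t) for i, t in enumerate([0.4, 1.2])]
        est = cohort_estimate(filter_cohort(records), params, phys, mode="pooled")
        direct = invert_air_concentration(0.8, params, phys)
        assert est.air_conc_mean == pytest.approx(direct, rel=1e-9)
        assert est.air_conc_sd == 0.0


class TestCohortCsv:
    def test_round_trip(self, tmp_path):
        records = fixture_cohort_41()
        path = tmp_path / "cohort.csv"
        write_cohort_csv(records, path)
        assert read_cohort_csv(path) == records

    def test_missing_ttma_allowed_when_censored(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "child_id,age_y,weight_kg,height_cm,ttma_mg_L,below_loq,creatinine_g_L,acr_mg_g,acr_normal\n"
            "K01,8,27,128,,true,1.0,10,true\n"
        )
        (rec,) = read_cohort_csv(path)
        assert rec.below_loq and rec.ttma == 0.0

    def test_missing_ttma_rejected_when_quantifiable(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "child_id,age_y,weight_kg,height_cm,ttma_mg_L,below_loq,creatinine_g_L,acr_mg_g,acr_normal\n"
            "K01,8,27,128,,false,1.0,10,true\n"
        )
        with pytest.raises(CohortSchemaError, match="row 2"):
            read_cohort_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("child_id,age_y\nK01,8\n")
        with pytest.raises(CohortSchemaError):
            read_cohort_csv(path)
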