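"""Eligibility cascade rules: diagnosis criterion, index determination,
enrollment, exclusions, baseline covariates, attrition."""

import numpy as np
import pandas as pd
import pytest

from mrcc_claims.charlson import compute_dcci
from mrcc_claims.cohort_builder import (
    apply_exclusions,
    build_cohort,
    check_enrollment,
    derive_baseline_covariates,
    determine_index,
    find_mrcc_patients,
)
from mrcc_claims.synthetic_claims import SimConfig, generate

from conftest import d, dx, iv, make_bundle, proc, rx


def drug_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "agent", "days_supply", "source"])
    return df.sort_values("date").reset_index(drop=True)


def med_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "code", "kind"])
    df["claim_id"] = np.arange(len(df))
    return df


class TestFindMrcc:
    @pytest.mark.parametrize(
        "offsets, expected",
        [((0, 30), True), ((0, 10), False), ((0,), False),
         ((0, 10, 40), True), ((0, 29), False)],
    )
    def test_day_spacing_rule(self, study, offsets, expected):
        bundle = make_bundle(
            [{"patient_id": "a", "start_date": d(-400), "end_date": d(400)}],
            [dx("a", d(o), "1890") for o in offsets],
            [],
        )
        found = find_mrcc_patients(bundle, study.kidney, study.params.dx_window)
        assert ("a" in found) is expected
        if expected:
            assert found["a"] == d(offsets[0])

    def test_non_kidney_codes_ignored(self, study):
        bundle = make_bundle(
            [{"patient_id": "a", "start_date": d(-400), "end_date": d(400)}],
            [dx("a", d(0), "174"), dx("a", d(40), "174")],
            [],
        )
        assert find_mrcc_patients(bundle, study.kidney, study.params.dx_window) == {}


class TestDetermineIndex:
    def test_two_agents_within_five_days_excluded(self, study):
        claims = drug_frame([rx("a", d(0), "sunitinib"), rx("a", d(3), "everolimus")])
        res = determine_index(claims, d(-14), study.params, study.catalog)
        assert res.five_day_excluded

    def test_combination_indexed_at_first_claim(self, study):
        claims = drug_frame([iv("a", d(0), "bevacizumab"), iv("a", d(20), "ifn_alfa")])
        res = determine_index(claims, d(-14), study.params, study.catalog)
        assert res.index_agent == "bevacizumab+ifn_alfa"
        assert res.index_date == d(0)
        assert not res.five_day_excluded

    def test_ifn_first_still_combination(self, study):
        claims = drug_frame([iv("a", d(0), "ifn_alfa"), iv("a", d(25), "bevacizumab")])
        res = determine_index(claims, d(-14), study.params, study.catalog)
        assert res.index_agent == "bevacizumab+ifn_alfa"
        assert res.index_date == d(0)

    def test_ifn_alone_never_indexes(self, study):
        claims = drug_frame([iv("a", d(0), "ifn_alfa"), iv("a", d(7), "ifn_alfa")])
        assert determine_index(claims, d(-14), study.params, study.catalog) is None

    def test_replacement_with_refill(self, study):
        claims = drug_frame(
            [rx("a", d(0), "sorafenib"), rx("a", d(20), "pazopanib"),
             rx("a", d(50), "pazopanib")]
        )
        res = determine_index(claims, d(-14), study.params, study.catalog)
        assert (res.index_agent, res.index_date, res.replaced) == ("pazopanib", d(20), True)

    def test_no_refill_no_replacement(self, study):
        claims = drug_frame(
            [rx("a", d(0), "sorafenib"), rx("a", d(20), "pazopanib")]
        )
        res = determine_index(claims, d(-14), study.params, study.catalog)
        assert (res.index_agent, res.replaced) == ("sorafenib", False)

    def test_first_ever_claim_outside_window_disqualifies(self, study):
        # first-ever claim 2010: before the 2011-2015 index period
        early = pd.Timestamp("2010-06-01")
        claims = drug_frame(
            [rx("a", early, "sunitinib"), rx("a", d(0), "sunitinib")]
        )
        assert determine_index(claims, d(-14), study.params, study.catalog) is None

    def test_claim_too_long_before_first_mrcc_disqualifies(self, study):
        claims = drug_frame([rx("a", d(0), "sunitinib")])
        assert determine_index(claims, d(45), study.params, study.catalog) is None
        assert determine_index(claims, d(30), study.params, study.catalog) is not None


class TestEnrollment:
    def span(self, lo, hi):
        return make_bundle(
            [{"patient_id": "a", "start_date": lo, "end_date": hi}], [], []
        ).enrollment

    def test_covering_span_passes(self, study):
        assert check_enrollment(self.span(d(-400), d(400)), d(0), study.params) is not None

    def test_pre_index_shortfall_fails(self, study):
        assert check_enrollment(self.span(d(-100), d(400)), d(0), study.params) is None

    def test_exact_window_boundary_inclusive(self, study):
        assert check_enrollment(self.span(d(-180), d(180)), d(0), study.params) is not None
        assert check_enrollment(self.span(d(-179), d(180)), d(0), study.params) is None

    def test_adjacent_spans_merge_then_cover(self, study):
        enr = make_bundle(
            [
                {"patient_id": "a", "start_date": d(-400), "end_date": d(-10)},
                {"patient_id": "a", "start_date": d(-9), "end_date": d(400)},
            ],
            [], [],
        ).enrollment
        assert len(enr) == 1  # normalization merged them
        assert check_enrollment(enr, d(0), study.params) is not None

    def test_post_requirement_relaxed_for_trend_cohort(self, study):
        enr = self.span(d(-200), d(10))
        assert check_enrollment(enr, d(0), study.params) is None
        assert check_enrollment(enr, d(0), study.params, require_post=False) is not None


class TestExclusions:
    def test_tcc_agent_during_followup_excludes(self, study):
        drug = drug_frame([rx("a", d(0), "sunitinib"), iv("a", d(200), "gemcitabine")])
        ok, reasons = apply_exclusions(drug, med_frame([]), d(0), d(400), study)
        assert not ok and reasons == ["tcc_agent"]

    def test_tcc_agent_before_window_ignored(self, study):
        drug = drug_frame([rx("a", d(0), "sunitinib"), iv("a", d(-60), "gemcitabine")])
        ok, _ = apply_exclusions(drug, med_frame([]), d(0), d(400), study)
        assert ok

    def test_two_breast_primary_claims_exclude(self, study):
        med = med_frame([dx("a", d(-100), "174"), dx("a", d(-50), "174")])
        ok, reasons = apply_exclusions(drug_frame([]), med, d(0), d(400), study)
        assert not ok and reasons == ["other_primary:breast"]

    def test_single_primary_claim_keeps_patient(self, study):
        med = med_frame([dx("a", d(-100), "174")])
        ok, _ = apply_exclusions(drug_frame([]), med, d(0), d(400), study)
        assert ok

    def test_lung_metastasis_site_not_excluding(self, study):
        """Secondary lung codes are RCC metastases, not another primary."""
        med = med_frame([dx("a", d(-100), "1970"), dx("a", d(-50), "1970")])
        ok, _ = apply_exclusions(drug_frame([]), med, d(0), d(400), study)
        assert ok


class TestBaselineCovariates:
    def test_lung_metastasis_flag(self, study):
        med = med_frame([dx("a", d(-30), "1970")])
        cov = derive_baseline_covariates(med, d(0), study)
        assert cov["met_lung"] and not cov["met_liver"]

    def test_dcci_diabetes_plus_chf(self, study):
        med = med_frame([dx("a", d(-30), "250"), dx("a", d(-30), "428")])
        cov = derive_baseline_covariates(med, d(0), study)
        assert cov["dcci"] == 2 and cov["diabetes"] and cov["chf"]

    def test_no_claims_all_false(self, study):
        cov = derive_baseline_covariates(med_frame([]), d(0), study)
        assert cov["dcci"] == 0
        assert not any(cov[k] for k in study.comorbidity)
        assert not cov["nephrectomy"]

    def test_nephrectomy_from_procedure(self, study):
        med = med_frame([proc("a", d(-100), "50220")])
        assert derive_baseline_covariates(med, d(0), study)["nephrectomy"]

    def test_outside_baseline_window_ignored(self, study):
        med = med_frame([dx("a", d(-200), "428"), dx("a", d(5), "250")])
        cov = derive_baseline_covariates(med, d(0), study)
        assert not cov["chf"] and not cov["diabetes"] and cov["dcci"] == 0


def test_dcci_hierarchy_rules():
    # severe liver supersedes mild; complicated diabetes supersedes plain
    assert compute_dcci(["571", "5722"]) == 3
    assert compute_dcci(["250", "2504"]) == 2
    assert compute_dcci(["042"]) == 6


class TestBuildCohort:
    def test_generator_truth_recovered(self, study):
        cfg = SimConfig(
            n_patients=250, seed=21,
            frac_single_dx=0.05, frac_underage=0.05, frac_enrollment_gap=0.05,
            frac_tcc=0.05, frac_other_primary=0.05, frac_five_day=0.05,
            frac_index_replacement=0.08,
        )
        bundle, truth = generate(cfg, study)
        cohort, report = build_cohort(bundle, study)
        t = truth.patients.set_index("patient_id")
        elig = t[t["eligible"]]
        assert set(cohort["patient_id"]) == set(elig.index)
        co = cohort.set_index("patient_id")
        assert (co["index_date"] == elig.loc[co.index, "index_date"]).all()
        assert (co["index_agent"] == elig.loc[co.index, "index_agent"]).all()
        assert (co["dcci"] == elig.loc[co.index, "dcci_true"]).all()
        for flag in ("chf", "diabetes", "met_bone", "met_liver", "nephrectomy"):
            assert (co[flag] == elig.loc[co.index, flag]).all()
        assert report["patients_remaining"].is_monotonic_decreasing

    def test_rule_by_rule_independent_oracle(self, study):
        """Cohort membership equals the intersection of per-rule truth sets."""
        cfg = SimConfig(
            n_patients=200, seed=22, frac_single_dx=0.1, frac_tcc=0.1,
            frac_underage=0.1, frac_other_primary=0.1,
        )
        bundle, truth = generate(cfg, study)
        cohort, _ = build_cohort(bundle, study)
        t = truth.patients
        per_rule = [set(t.loc[t["fault"] != f, "patient_id"])
                    for f in ("single_dx", "underage", "tcc", "other_primary")]
        expected = set.intersection(*per_rule)
        assert set(cohort["patient_id"]) == expected

    def test_empty_bundle_gives_empty_cohort_not_error(self, study):
        bundle = make_bundle(
            [{"patient_id": "a", "start_date": d(-400), "end_date": d(400)}],
            [dx("a", d(0), "1890")],  # single dx claim: fails criterion 1
            [],
        )
        cohort, report = build_cohort(bundle, study)
        assert cohort.empty
        assert report.iloc[0]["patients_remaining"] == 1
        assert report.iloc[-1]["patients_remaining"] == 0

    def test_all_eligible_attrition_constant(self, study):
        bundle, truth = generate(SimConfig(n_patients=80, seed=23), study)
        _, report = build_cohort(bundle, study)
        assert report["patients_remaining"].nunique() == 1
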