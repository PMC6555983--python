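"""Episode stitching, second-line detection, event construction, flow."""

import numpy as np
import pandas as pd
import pytest

from mrcc_claims.claims_model import ClaimsModelError
from mrcc_claims.lot_engine import (
    build_lines,
    claim_coverage_end,
    detect_second_line,
    duration_event,
    flow_table,
    stitch_episode,
    tt2t_event,
)
from mrcc_claims.synthetic_claims import SimConfig, generate

from conftest import d, iv, rx


def claims_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "agent", "days_supply", "source"])
    return df.sort_values("date").reset_index(drop=True)


class TestCoverageEnd:
    def test_oral_uses_days_supply(self, study):
        assert claim_coverage_end(d(60), "sunitinib", 30, study.catalog) == d(90)

    def test_iv_uses_cycle_length(self, study):
        assert claim_coverage_end(d(10), "temsirolimus", None, study.catalog) == d(17)

    def test_zero_supply_is_data_error(self, study):
        with pytest.raises(ClaimsModelError):
            claim_coverage_end(d(0), "sunitinib", 0, study.catalog)


class TestStitch:
    @pytest.mark.parametrize(
        "offsets, end_off, n, restart_off",
        [
            ((0, 30, 60), 90, 3, None),      # back-to-back fills
            ((0, 100), 130, 2, None),        # 70-day gap permitted
            ((0, 150), 30, 1, 150),          # 120-day gap terminates
            ((0,), 30, 1, None),
            ((0, 120, 150), 150 + 30, 3, None),  # 90-day gap is still permitted
        ],
    )
    def test_gap_rule(self, study, offsets, end_off, n, restart_off):
        claims = claims_frame([rx("a", d(o), "sunitinib") for o in offsets])
        st = stitch_episode(claims, d(0), study.params.gap_days, study.catalog)
        assert st.end == d(end_off)
        assert st.n_claims == n
        assert st.restart_date == (d(restart_off) if restart_off is not None else None)

    def test_early_refill_restarts_coverage_no_stockpile(self, study):
        claims = claims_frame(
            [rx("a", d(0), "sunitinib", 90), rx("a", d(10), "sunitinib", 10)]
        )
        st = stitch_episode(claims, d(0), study.params.gap_days, study.catalog)
        assert st.end == d(20)  # coverage follows the latest fill only

    def test_first_claim_must_anchor_index(self, study):
        claims = claims_frame([rx("a", d(5), "sunitinib")])
        with pytest.raises(ValueError):
            stitch_episode(claims, d(0), 90, study.catalog)


class TestSecondLine:
    def _stitch(self, study, claims, agent="sunitinib"):
        own = claims[claims["agent"] == agent].reset_index(drop=True)
        return stitch_episode(own, d(0), study.params.gap_days, study.catalog)

    def test_new_agent_after_30_days(self, study):
        claims = claims_frame(
            [rx("a", d(0), "sunitinib"), rx("a", d(120), "pazopanib")]
        )
        st = self._stitch(study, claims)
        tt, agent, start = detect_second_line(claims, st, d(0), "sunitinib", study)
        assert (tt, agent, start) == (120, "pazopanib", d(120))

    def test_restart_after_long_gap(self, study):
        claims = claims_frame(
            [rx("a", d(0), "sunitinib"), rx("a", d(150), "sunitinib")]
        )
        st = self._stitch(study, claims)
        tt, agent, start = detect_second_line(claims, st, d(0), "sunitinib", study)
        assert (tt, agent) == (150, "sunitinib")

    def test_no_further_claims_none(self, study):
        claims = claims_frame([rx("a", d(0), "sunitinib")])
        st = self._stitch(study, claims)
        assert detect_second_line(claims, st, d(0), "sunitinib", study) is None

    def test_new_agent_within_window_not_second_line(self, study):
        claims = claims_frame(
            [rx("a", d(0), "sunitinib", 60), rx("a", d(25), "pazopanib")]
        )
        st = self._stitch(study, claims)
        assert detect_second_line(claims, st, d(0), "sunitinib", study) is None

    def test_boundary_day_30_exclusive(self, study):
        claims = claims_frame(
            [rx("a", d(0), "sunitinib", 60), rx("a", d(30), "pazopanib"),
             rx("a", d(31), "everolimus")]
        )
        st = self._stitch(study, claims)
        tt, agent, _ = detect_second_line(claims, st, d(0), "sunitinib", study)
        assert (tt, agent) == (31, "everolimus")

    def test_ifn_alone_not_a_second_line(self, study):
        claims = claims_frame(
            [rx("a", d(0), "sunitinib"), iv("a", d(100), "ifn_alfa")]
        )
        st = self._stitch(study, claims)
        assert detect_second_line(claims, st, d(0), "sunitinib", study) is None


class TestEvents:
    def mk_stitch(self, study, end_off):
        claims = claims_frame([rx("a", d(0), "sunitinib", end_off)])
        return stitch_episode(claims, d(0), study.params.gap_days, study.catalog)

    def test_switch_event_at_episode_end(self, study):
        st = self.mk_stitch(study, 90)
        assert duration_event(st, d(120), d(0), d(300), 90) == (90, True, "switch")

    def test_overlapping_switch_truncates(self, study):
        st = self.mk_stitch(study, 90)
        assert duration_event(st, d(60), d(0), d(300), 90) == (60, True, "switch")

    def test_discontinuation_event(self, study):
        st = self.mk_stitch(study, 90)
        assert duration_event(st, None, d(0), d(300), 90) == (
            90, True, "discontinuation"
        )

    def test_censored_near_enrollment_end(self, study):
        st = self.mk_stitch(study, 250)
        assert duration_event(st, None, d(0), d(300), 90) == (300, False, "censored")

    def test_tt2t_event_and_censoring(self, study):
        st = self.mk_stitch(study, 90)
        assert tt2t_event(st, 120, d(0), d(300)) == (120, True)
        assert tt2t_event(st, None, d(0), d(300)) == (90, False)
        st2 = self.mk_stitch(study, 400)
        assert tt2t_event(st2, None, d(0), d(300)) == (300, False)


@pytest.fixture(scope="module")
def run(study):
    from mrcc_claims.cohort_builder import build_cohort

    bundle, truth = generate(SimConfig(n_patients=300, seed=31), study)
    cohort, _ = build_cohort(bundle, study)
    episodes, events = build_lines(cohort, bundle, study)
    return cohort, episodes, events, truth


class TestBuildLinesIntegration:
    def test_conservation(self, run):
        cohort, episodes, events, _ = run
        for endpoint in ("duration", "tt2t"):
            assert (events["endpoint"] == endpoint).sum() == len(cohort)
        flow = flow_table(cohort, episodes)
        assert int(flow.to_numpy().sum()) == len(cohort)
        assert int(flow.drop(columns="none", errors="ignore").to_numpy().sum()) == (
            episodes["line"] == 2
        ).sum()

    def test_line1_starts_at_index(self, run):
        cohort, episodes, _, _ = run
        e1 = episodes[episodes["line"] == 1].set_index("patient_id")
        co = cohort.set_index("patient_id")
        assert (e1["start_date"] == co.loc[e1.index, "index_date"]).all()

    def test_switch_tt2t_exceeds_30_days(self, run):
        """Any different-agent 2L obeys the > 30-day switch rule."""
        cohort, episodes, events, _ = run
        e2 = episodes[episodes["line"] == 2].merge(
            cohort[["patient_id", "index_agent", "index_date"]], on="patient_id"
        )
        diff = e2[e2["agent"] != e2["index_agent"]]
        days = (diff["start_date"] - diff["index_date"]).dt.days
        assert (days > 30).all()

    def test_ground_truth_recovery(self, run):
        cohort, episodes, _, truth = run
        t = truth.patients.set_index("patient_id")
        e1 = episodes[episodes["line"] == 1].set_index("patient_id")
        assert (e1["coverage_end"] == t.loc[e1.index, "line1_end"]).all()
        e2 = episodes[episodes["line"] == 2].set_index("patient_id")
        t2 = t.loc[cohort["patient_id"]]
        t2 = t2[t2["line2_start"].notna()]
        assert set(e2.index) == set(t2.index)
        assert (e2["start_date"] == t2.loc[e2.index, "line2_start"]).all()
        assert (e2["agent"] == t2.loc[e2.index, "line2_agent"]).all()


def test_flow_table_hand_count():
    cohort = pd.DataFrame(
        {"patient_id": list("abcd"), "index_agent": ["sunitinib"] * 4}
    )
    episodes = pd.DataFrame(
        {
            "patient_id": list("abc"),
            "line": [2, 2, 2],
            "agent": ["everolimus"] * 3,
        }
    )
    table = flow_table(cohort, episodes)
    assert table.loc["sunitinib", "everolimus"] == 3
    assert table.loc["sunitinib", "none"] == 1
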