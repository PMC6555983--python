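"""Code normalization, prefix matching, catalog, and bundle I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcc_claims.claims_model import (
    CatalogError,
    ClaimsModelError,
    CodeSet,
    DrugClass,
    Route,
    SchemaError,
    default_catalog,
    match_code,
    normalize_code,
    normalize_enrollment_spans,
    read_claims_bundle,
    write_claims_bundle,
)
from mrcc_claims.synthetic_claims import SimConfig, generate

from conftest import d


@pytest.mark.parametrize(
    "raw, expected",
    [("189.0", "1890"), ("c64.1", "C641"), ("197.0", "1970"),
     ("  J44 ", "J44"), ("0TT0", "0TT0")],
)
def test_normalize_code(raw, expected):
    assert normalize_code(raw) == expected


@pytest.mark.parametrize("bad", ["", "   ", None])
def test_normalize_code_rejects_empty(bad):
    with pytest.raises(ClaimsModelError):
        normalize_code(bad)


KIDNEY = CodeSet("kidney", ("1890", "C64"))


@pytest.mark.parametrize(
    "code, expected",
    [("C641", True), ("1890", True), ("1891", False), ("C64", True),
     ("C65", False), ("189", False)],
)
def test_match_code_prefix_semantics(code, expected):
    assert match_code(code, KIDNEY) is expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    code=st.text(alphabet="0123456789ABCX", min_size=1, max_size=6),
    prefixes=st.lists(
        st.text(alphabet="0123456789ABCX", min_size=1, max_size=4),
        min_size=1, max_size=5,
    ),
)
def test_match_code_equals_bruteforce(code, prefixes):
    cs = CodeSet("any", tuple(prefixes))
    assert match_code(code, cs) == any(code.startswith(p) for p in cs.prefixes)


class TestCatalog:
    def test_classification_examples(self, study):
        cat = study.catalog
        assert cat.classify_agent("sunitinib") == (DrugClass.TK_VEGF, Route.ORAL)
        assert cat.classify_agent("temsirolimus") == (DrugClass.MTOR, Route.IV)
        assert cat.classify_agent("everolimus") == (DrugClass.MTOR, Route.ORAL)
        assert cat.classify_agent("aldesleukin") == (DrugClass.IL2, Route.IV)

    def test_every_agent_classified_once(self, study):
        for entry in study.catalog:
            cls, route = study.catalog.classify_agent(entry.agent)
            assert isinstance(cls, DrugClass) and isinstance(route, Route)
            if route is Route.ORAL:
                assert entry.cycle_length_days is None
            else:
                assert entry.cycle_length_days >= 1

    def test_unknown_agent_errors(self, study):
        with pytest.raises(CatalogError, match="nivolumab"):
            study.catalog.classify_agent("nivolumab")

    def test_ifn_never_indexable_alone(self, study):
        assert "ifn_alfa" not in study.catalog.indexable_agents()

    def test_oral_coverage_requires_supply(self, study):
        with pytest.raises(ClaimsModelError):
            study.catalog.coverage_days("sunitinib", None)
        with pytest.raises(ClaimsModelError):
            study.catalog.coverage_days("sunitinib", 0)
        assert study.catalog.coverage_days("temsirolimus", None) == 7


class TestEnrollmentNormalization:
    def test_adjacent_spans_merge(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "a"],
                "start_date": [d(-400), d(-9)],
                "end_date": [d(-10), d(400)],
            }
        )
        out = normalize_enrollment_spans(df)
        assert len(out) == 1
        assert out.loc[0, "start_date"] == d(-400)
        assert out.loc[0, "end_date"] == d(400)

    def test_gapped_spans_stay_separate(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "a"],
                "start_date": [d(-400), d(-7)],
                "end_date": [d(-10), d(400)],
            }
        )
        assert len(normalize_enrollment_spans(df)) == 2

    def test_bad_span_raises(self):
        df = pd.DataFrame(
            {"patient_id": ["a"], "start_date": [d(5)], "end_date": [d(0)]}
        )
        with pytest.raises(SchemaError):
            normalize_enrollment_spans(df)


class TestBundleIO:
    def test_round_trip_identity(self, tmp_path, study):
        bundle, _ = generate(SimConfig(n_patients=25, seed=7), study)
        write_claims_bundle(bundle, tmp_path)
        back = read_claims_bundle(tmp_path, study.catalog, extra_agents=study.tcc_agents)
        pd.testing.assert_frame_equal(
            bundle.enrollment.reset_index(drop=True), back.enrollment
        )
        pd.testing.assert_frame_equal(
            bundle.drug.reset_index(drop=True), back.drug,
        )
        # codes survive (claim ids may be renumbered)
        a = bundle.medical[["patient_id", "date", "code", "kind"]].sort_values(
            ["patient_id", "date", "code"]).reset_index(drop=True)
        b = back.medical[["patient_id", "date", "code", "kind"]].sort_values(
            ["patient_id", "date", "code"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        # write->read->write is byte-stable
        write_claims_bundle(back, tmp_path / "again")
        for f in ("enrollment.csv", "medical.csv", "pharmacy.csv", "administration.csv"):
            assert (tmp_path / f).read_bytes() == (tmp_path / "again" / f).read_bytes()

    def test_bad_date_row_dropped_with_warning(self, tmp_path, study):
        bundle, _ = generate(SimConfig(n_patients=5, seed=7), study)
        write_claims_bundle(bundle, tmp_path)
        rxf = tmp_path / "pharmacy.csv"
        lines = rxf.read_text().splitlines()
        parts = lines[1].split(",")
        parts[1] = "not-a-date"
        lines[1] = ",".join(parts)
        rxf.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError):
            read_claims_bundle(tmp_path, study.catalog, strict=True,
                               extra_agents=study.tcc_agents)
        back = read_claims_bundle(tmp_path, study.catalog, strict=False,
                                  extra_agents=study.tcc_agents)
        n_rx = (back.drug["source"] == "pharmacy").sum()
        assert n_rx == (bundle.drug["source"] == "pharmacy").sum() - 1
        assert any("not-a-date" in i.message for i in back.issues)

    def test_unknown_agent_named_in_error(self, tmp_path, study):
        bundle, _ = generate(SimConfig(n_patients=5, seed=7), study)
        bundle.drug.loc[0, "agent"] = "mystery_drug"
        write_claims_bundle(bundle, tmp_path)
        with pytest.raises(CatalogError, match="mystery_drug"):
            read_claims_bundle(tmp_path, study.catalog, extra_agents=study.tcc_agents)

    def test_missing_column_is_schema_error(self, tmp_path, study):
        bundle, _ = generate(SimConfig(n_patients=5, seed=7), study)
        write_claims_bundle(bundle, tmp_path)
        f = tmp_path / "pharmacy.csv"
        df = pd.read_csv(f).drop(columns=["days_supply"])
        df.to_csv(f, index=False)
        with pytest.raises(SchemaError, match="days_supply"):
            read_claims_bundle(tmp_path, study.catalog, extra_agents=study.tcc_agents)
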