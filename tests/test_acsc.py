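"""ACSC catalogue loading, code classification, and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ahspatial as ah
from ahspatial.acsc import AcscParseError, expand_pattern


@pytest.fixture(scope="module")
def table():
    return ah.load_acsc_table()


class TestCatalogue:
    def test_builtin_contains_expected_conditions(self, table):
        by_name = {e.condition: e for e in table}
        copd = by_name["COPD"]
        assert copd.classification == "chronic"
        assert "J44" in copd.code_patterns
        gang = by_name["Gangrene"]
        assert gang.classification == "acute"
        assert gang.code_patterns == ("R02",)

    def test_range_patterns_expand_inclusively(self):
        assert expand_pattern("E10.0-10.8") == [f"E10.{d}" for d in range(9)]
        assert expand_pattern("K25.4-25.6") == ["K25.4", "K25.5", "K25.6"]

    def test_malformed_patterns_raise_naming_the_pattern(self):
        with pytest.raises(AcscParseError, match="E10"):
            expand_pattern("E10.8-10.0")
        with pytest.raises(AcscParseError, match="banana"):
            expand_pattern("banana")

    def test_empty_file_is_a_parse_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("condition,classification,patterns\n")
        with pytest.raises(AcscParseError):
            ah.load_acsc_table(p)

    def test_csv_round_trip(self, table, tmp_path):
        from ahspatial.acsc import write_acsc_table

        p = tmp_path / "acsc.csv"
        write_acsc_table(table, p)
        again = ah.load_acsc_table(p)
        assert [(e.condition, e.classification, e.resolved_prefixes) for e in again] == [
            (e.condition, e.classification, e.resolved_prefixes) for e in table
        ]

    def test_acute_and_chronic_sets_disjoint_by_exhaustive_expansion(self, table):
        # expand every prefix to the finest subcode grid and intersect
        def blow_up(prefixes):
            out = set()
            for p in prefixes:
                if len(p) == 3:
                    out |= {p} | {f"{p}.{d}" for d in range(10)}
                else:
                    out.add(p)
            return out

        acute = blow_up(
            p for e in table if e.classification == "acute" for p in e.resolved_prefixes
        )
        chronic = blow_up(
            p for e in table if e.classification == "chronic" for p in e.resolved_prefixes
        )
        assert not acute & chronic


class TestClassify:
    @pytest.mark.parametrize(
        "code,expected_class,expected_condition",
        [
            ("E10.3", "chronic", "Diabetes"),
            ("I20.9", "acute", "Angina"),  # prefix match on I20
            ("Z00", "none", None),
            ("E10.9", "none", None),  # range E10.0-10.8 excludes .9
            ("E10.8", "chronic", "Diabetes"),
            ("J45", "chronic", "Asthma"),
            ("J450", "chronic", "Asthma"),  # undotted normalisation
            ("n30.0", "acute", "Urinary tract infection"),
            ("I24.1", "none", None),  # angina lists only I24.0/.8/.9
            ("K25.3", "none", None),  # ulcer ranges skip .3 (haemorrhage+perforation)
            ("I11.0", "chronic", "Congestive heart failure"),
            ("I11.9", "chronic", "Hypertension"),
        ],
    )
    def test_classification_examples(self, table, code, expected_class, expected_condition):
        cls, cond = ah.classify_code(code, table)
        assert cls == expected_class
        assert cond == expected_condition

    def test_unparseable_code_warns_and_returns_none(self, table, caplog):
        with caplog.at_level("WARNING"):
            cls, cond = ah.classify_code("??", table)
        assert (cls, cond) == ("none", None)
        assert "unparseable" in caplog.text


class TestAggregate:
    def _general(self, rows):
        return pd.DataFrame(rows, columns=["district_id", "year", "general_hosp"])

    def test_share_arithmetic(self):
        recs = [
            ah.DischargeRecord("D1", 2010, "J45", 3),
            ah.DischargeRecord("D1", 2010, "N30.0", 1),
        ]
        out = ah.aggregate(recs, self._general([("D1", 2010, 40)]))
        row = out.iloc[0]
        assert row.ah_total == 4 and row.ah_chronic == 3 and row.ah_acute == 1
        assert row.share_total == pytest.approx(0.10)
        assert row.share_chronic == pytest.approx(0.075)
        assert row.share_acute == pytest.approx(0.025)

    def test_zero_fill_for_silent_cells(self):
        recs = [ah.DischargeRecord("D1", 2010, "J45", 3)]
        out = ah.aggregate(
            recs, self._general([("D1", 2010, 40), ("D2", 2010, 50)])
        )
        d2 = out[out.district_id == "D2"].iloc[0]
        assert d2.ah_total == 0 and d2.share_total == 0.0

    def test_share_above_one_rejected(self):
        recs = [ah.DischargeRecord("D1", 2010, "J45", 50)]
        with pytest.raises(ValueError, match="exceeds"):
            ah.aggregate(recs, self._general([("D1", 2010, 40)]))

    def test_missing_general_count_is_keyed_error(self):
        recs = [ah.DischargeRecord("D9", 2011, "J45", 1)]
        with pytest.raises(KeyError, match="D9"):
            ah.aggregate(recs, self._general([("D1", 2010, 40)]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_record_order_never_changes_aggregates(self, rand):
        codes = ["J45", "N30.0", "Z00", "I20.9", "E10.8", "C50.9"]
        recs = [
            ah.DischargeRecord(f"D{i % 2}", 2010, codes[i % len(codes)], i % 5)
            for i in range(12)
        ]
        general = self._general([("D0", 2010, 100), ("D1", 2010, 100)])
        base = ah.aggregate(recs, general)
        shuffled = list(recs)
        rand.shuffle(shuffled)
        pd.testing.assert_frame_equal(base, ah.aggregate(shuffled, general))

    def test_counts_split_into_acute_plus_chronic(self, table):
        cfg = ah.SyntheticConfig(n_districts=4, n_years=2, seed=9)
        records, truth = ah.generate_discharges(cfg, table)
        recs = [
            ah.DischargeRecord(r.district_id, int(r.year), r.icd10, int(r.count))
            for r in records.itertuples()
        ]
        out = ah.aggregate(
            recs, truth[["district_id", "year", "general_hosp"]], table
        )
        assert (out.ah_total == out.ah_acute + out.ah_chronic).all()
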