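"""Screen-record validation, capping, filtering and min-growth aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comboscreen.screen import (
    InvalidMeasurementError,
    aggregate_min_growth,
    canonical_pair_key,
    cap_growth,
    filter_records,
    read_screen,
    validate_screen,
    write_screen,
)


def make_records(rows):
    df = pd.DataFrame(rows, columns=["CELL", "DRUG_A", "DRUG_B", "DOSE_A", "DOSE_B", "GROWTH", "QC"])
    return validate_screen(df)


class TestCapGrowth:
    @pytest.mark.parametrize(
        "raw, capped",
        [(1.3, 1.0), (0.5, 0.5), (-1.0, -1.0), (1.0, 1.0), (0.0, 0.0)],
    )
    def test_caps_above_one_only(self, raw, capped):
        assert cap_growth(raw) == capped

    def test_below_minus_one_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            cap_growth(-1.01)

    @given(st.floats(min_value=-1.0, max_value=2.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_bounded(self, g):
        once = cap_growth(g)
        assert cap_growth(once) == once
        assert -1.0 <= once <= 1.0

    def test_vectorized(self):
        out = cap_growth(np.array([1.2, 0.3, -0.5]))
        np.testing.assert_allclose(out, [1.0, 0.3, -0.5])


class TestFilterRecords:
    @pytest.fixture
    def records(self):
        return make_records([
            ("C1", "A", "B", 0, 0, 0.5, True),
            ("C1", "A", "B", 1, 0, 0.4, False),
            ("C1", "A", None, 0, None, 0.9, True),
            ("C2", "A", "C", 0, 0, 0.2, False),
            ("C2", "C", None, 0, None, 0.7, True),
        ])

    def test_qc_flag(self, records):
        assert len(filter_records(records, require_qc=True)) == 3

    def test_no_op(self, records):
        out = filter_records(records)
        pd.testing.assert_frame_equal(out, records)

    def test_allowed_drugs_applies_to_both_slots(self, records):
        out = filter_records(records, allowed_drugs={"A", "B"})
        assert set(out["DRUG_A"]) == {"A"}
        assert len(out) == 3  # the A+C pair and the C single are gone

    def test_all_cells_excluded(self, records):
        assert filter_records(records, excluded_cells={"C1", "C2"}).empty


class TestAggregateMinGrowth:
    def test_minimum_over_dose_grid(self):
        recs = make_records([
            ("C1", "A", "B", i, j, g, True)
            for (i, j), g in zip([(0, 0), (0, 1), (1, 0), (1, 1)], [0.8, 0.3, -0.2, 0.5])
        ])
        out = aggregate_min_growth(recs)
        assert len(out) == 1
        assert out["MIN_GROWTH"].iloc[0] == pytest.approx(-0.2)

    def test_singleton_and_constant_groups(self):
        recs = make_records(
            [("C1", "A", None, 0, None, 0.4, True)]
            + [("C1", "A", "B", i, j, 0.7, True) for i in range(3) for j in range(3)]
        )
        out = aggregate_min_growth(recs)
        single = out[out["DRUG_B"].isna()]["MIN_GROWTH"].iloc[0]
        pair = out[out["DRUG_B"].notna()]["MIN_GROWTH"].iloc[0]
        assert single == pytest.approx(0.4)
        assert pair == pytest.approx(0.7)

    def test_capping_applied_before_aggregation(self):
        recs = make_records([
            ("C1", "A", None, 0, None, 1.3, True),
            ("C1", "A", None, 1, None, 1.1, True),
        ])
        out = aggregate_min_growth(recs)
        assert out["MIN_GROWTH"].iloc[0] == pytest.approx(1.0)

    def test_conflicting_duplicates_raise_when_configured(self):
        recs = make_records([
            ("C1", "A", "B", 0, 0, 0.5, True),
            ("C1", "A", "B", 0, 0, 0.3, True),
        ])
        assert aggregate_min_growth(recs)["MIN_GROWTH"].iloc[0] == pytest.approx(0.3)
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_min_growth(recs, on_duplicate="raise")

    @given(st.lists(
        st.tuples(
            st.sampled_from(["C1", "C2"]),
            st.sampled_from(["A", "B"]),
            st.sampled_from([None, "X"]),
            st.integers(0, 2),
            st.floats(min_value=-1, max_value=1.3, allow_nan=False),
        ),
        min_size=1, max_size=30,
    ))
    @settings(max_examples=100, deadline=None)
    def test_one_row_per_tuple_and_lower_bound(self, rows):
        """Brute-force oracle: group-and-min over capped growth."""
        recs = make_records([
            (c, a, b, d, 0 if b else None, g, True) for c, a, b, d, g in rows
        ])
        out = aggregate_min_growth(recs)
        groups = {}
        for c, a, b, _, g in rows:
            groups.setdefault((c, a, b), []).append(min(g, 1.0))
        assert len(out) == len(groups)
        for _, row in out.iterrows():
            key = (row["CELL"], row["DRUG_A"], None if pd.isna(row["DRUG_B"]) else row["DRUG_B"])
            assert row["MIN_GROWTH"] == pytest.approx(min(groups[key]))

    def test_filter_then_aggregate_commutes_for_tuple_level_filters(self):
        recs = make_records([
            ("C1", "A", "B", 0, 0, 0.5, True),
            ("C1", "A", "B", 1, 0, 0.1, True),
            ("C2", "A", "B", 0, 0, 0.7, True),
        ])
        a = aggregate_min_growth(filter_records(recs, excluded_cells={"C2"}))
        b = aggregate_min_growth(recs)
        b = b[b["CELL"] != "C2"].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestValidation:
    def test_single_agent_slots_must_be_consistent(self):
        with pytest.raises(ValueError, match="DOSE_B"):
            make_records([("C1", "A", None, 0, 1, 0.5, True)])
        with pytest.raises(ValueError, match="DOSE_B"):
            make_records([("C1", "A", "B", 0, None, 0.5, True)])

    def test_growth_below_minus_one_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            make_records([("C1", "A", None, 0, None, -1.5, True)])

    def test_identifiers_trimmed(self):
        recs = make_records([(" C1 ", " A ", None, 0, None, 0.5, True)])
        assert recs["CELL"].iloc[0] == "C1"
        assert recs["DRUG_A"].iloc[0] == "A"


def test_roundtrip_delimited(tmp_path):
    recs = make_records([
        ("C1", "A", "B", 0, 0, 0.5, True),
        ("C1", "A", None, 0, None, 0.9, False),
    ])
    path = tmp_path / "screen.csv"
    write_screen(recs, path)
    back = read_screen(path)
    assert len(back) == 2
    assert back["GROWTH"].tolist() == recs["GROWTH"].tolist()
    assert back["QC"].tolist() == [True, False]


def test_canonical_pair_key():
    assert canonical_pair_key("B", "A") == ("A", "B")
    assert canonical_pair_key("A", None) == ("A",)
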