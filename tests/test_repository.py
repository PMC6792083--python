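"""Repository wrapper: ordering, append-only re-analysis, round-trips."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from streamfdr import (
    DuplicateIdError,
    HypothesisRecord,
    ImmutabilityError,
    InvalidPValueError,
    OutOfOrderAppendError,
    ProcedureConfig,
    RepositoryResult,
    SpendingSequence,
    order_stream,
    records_from_frame,
    run_repository,
    update_repository,
)
from conftest import make_records

HALVING = SpendingSequence(values=0.5 ** np.arange(1, 13), kind="user")


class TestOrderStream:
    def test_same_seed_same_permutation(self):
        recs = make_records([("2020-01-01", 0.1)] * 8)
        a = order_stream(recs, seed=5)
        b = order_stream(recs, seed=5)
        assert [r.id for r in a] == [r.id for r in b]

    def test_appending_later_batch_preserves_earlier_order(self):
        base = make_records([("2020-01-01", 0.1)] * 6 + [("2020-01-02", 0.2)] * 6)
        grown = base + make_records([("2020-01-03", 0.3)] * 6, prefix="new")
        before = [r.id for r in order_stream(base, seed=9)]
        after = [r.id for r in order_stream(grown, seed=9)]
        assert after[: len(before)] == before

    def test_single_record_identity(self):
        recs = make_records([("2020-05-05", 0.5)])
        assert order_stream(recs, seed=0) == recs

    def test_duplicate_ids_rejected(self):
        recs = [
            HypothesisRecord(id="a", date=dt.date(2020, 1, 1), pval=0.1),
            HypothesisRecord(id="a", date=dt.date(2020, 1, 2), pval=0.2),
        ]
        with pytest.raises(DuplicateIdError):
            order_stream(recs, seed=0)

    def test_explicit_order_bypasses_randomization(self):
        recs = [
            HypothesisRecord(id=f"x{i}", date=dt.date(2020, 1, 1), pval=0.1, order=o)
            for i, o in enumerate([3, 1, 2])
        ]
        assert [r.id for r in order_stream(recs, seed=123)] == ["x1", "x2", "x0"]

    def test_partial_explicit_order_is_an_error(self):
        recs = [
            HypothesisRecord(id="a", date=dt.date(2020, 1, 1), pval=0.1, order=1),
            HypothesisRecord(id="b", date=dt.date(2020, 1, 1), pval=0.1),
        ]
        with pytest.raises(ValueError):
            order_stream(recs, seed=0)

    def test_dates_sort_ascending(self):
        recs = make_records([("2020-03-01", 0.2), ("2020-01-01", 0.1), ("2020-02-01", 0.3)])
        assert [r.date.month for r in order_stream(recs, seed=1)] == [1, 2, 3]


class TestRecordsFromFrame:
    def test_bad_pvalue_names_row(self):
        df = pd.DataFrame({"id": ["a", "b"], "date": ["2020-01-01"] * 2, "pval": [0.5, 1.5]})
        with pytest.raises(InvalidPValueError, match="row 3"):
            records_from_frame(df)

    def test_bad_date_rejected(self):
        df = pd.DataFrame({"id": ["a"], "date": ["not-a-date"], "pval": [0.5]})
        with pytest.raises(Exception, match="date"):
            records_from_frame(df)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="pval"):
            records_from_frame(pd.DataFrame({"id": ["a"], "date": ["2020-01-01"]}))


class TestRunRepository:
    def test_alpha_spending_thresholds_follow_permutation(self):
        recs = make_records([("2020-01-01", 0.5)] * 3)
        cfg = ProcedureConfig(alpha=0.05, variant="alpha_spending", gamma=HALVING)
        result = run_repository(recs, cfg, seed=7)
        np.testing.assert_allclose(
            result.frame["alphai"], [0.025, 0.0125, 0.00625], atol=1e-15, rtol=0
        )
        assert list(result.frame["id"]) == [r.id for r in order_stream(recs, seed=7)]
        assert sorted(result.frame["index"]) == [1, 2, 3]

    def test_empty_repository(self):
        cfg = ProcedureConfig(variant="lond")
        result = run_repository([], cfg, seed=1)
        assert len(result.frame) == 0
        assert result.metadata["procedure"] == "lond"

    def test_metadata_records_run_conditions(self):
        recs = make_records([("2020-01-01", 0.5)])
        cfg = ProcedureConfig(alpha=0.1, variant="lord2", w0=0.01)
        meta = run_repository(recs, cfg, seed=3).metadata
        assert meta["alpha"] == 0.1 and meta["w0"] == 0.01 and meta["seed"] == 3
        assert meta["gamma_kind"] == "lord_default"


class TestUpdateRepository:
    def _cfg(self):
        return ProcedureConfig(alpha=0.05, variant="lond", gamma=HALVING)

    def _base(self):
        # one batch of three: the hand-checked LOND stream, explicit order
        return [
            HypothesisRecord("a", dt.date(2019, 1, 1), 0.01, order=1),
            HypothesisRecord("b", dt.date(2019, 1, 1), 0.02, order=2),
            HypothesisRecord("c", dt.date(2019, 1, 1), 0.2, order=3),
        ]

    def test_append_nothing_is_identity(self):
        prev = run_repository(self._base(), self._cfg(), seed=0)
        out = update_repository(prev, self._base(), self._cfg(), seed=0)
        pd.testing.assert_frame_equal(out.frame, prev.frame, check_exact=True)

    def test_append_continues_the_recursion(self):
        prev = run_repository(self._base(), self._cfg(), seed=0)
        grown = self._base() + [HypothesisRecord("d", dt.date(2019, 2, 1), 0.5)]
        out = update_repository(prev, grown, self._cfg(), seed=0)
        pd.testing.assert_frame_equal(out.frame.iloc[:3].reset_index(drop=True), prev.frame, check_exact=True)
        # D(3) = 2 discoveries, so alpha_4 = 0.05 * gamma_4 * 3
        assert out.frame["alphai"].iloc[3] == pytest.approx(0.05 * 0.5**4 * 3, abs=1e-15)

    def test_same_or_earlier_dated_append_rejected(self):
        prev = run_repository(self._base(), self._cfg(), seed=0)
        for when in (dt.date(2019, 1, 1), dt.date(2018, 12, 31)):
            grown = self._base() + [HypothesisRecord("d", when, 0.5)]
            with pytest.raises(OutOfOrderAppendError):
                update_repository(prev, grown, self._cfg(), seed=0)

    def test_changed_pvalue_rejected(self):
        prev = run_repository(self._base(), self._cfg(), seed=0)
        tampered = self._base()
        tampered[1] = HypothesisRecord("b", dt.date(2019, 1, 1), 0.03, order=2)
        with pytest.raises(ImmutabilityError):
            update_repository(prev, tampered, self._cfg(), seed=0)

    def test_missing_previous_record_rejected(self):
        prev = run_repository(self._base(), self._cfg(), seed=0)
        with pytest.raises(ImmutabilityError):
            update_repository(prev, self._base()[:2], self._cfg(), seed=0)

    def test_changed_configuration_rejected(self):
        prev = run_repository(self._base(), self._cfg(), seed=0)
        other = ProcedureConfig(alpha=0.01, variant="lond", gamma=HALVING)
        with pytest.raises(ValueError, match="configuration"):
            update_repository(prev, self._base(), other, seed=0)


class TestAppendConsistency:
    @pytest.mark.parametrize("variant", ["lond", "lord2", "lord_pp", "alpha_spending"])
    def test_every_date_split_reproduces_prefix(self, variant, random_dated_records):
        """run(whole) restricted to any date prefix equals run(prefix)."""
        cfg = ProcedureConfig(alpha=0.05, variant=variant)
        whole = run_repository(random_dated_records, cfg, seed=11)
        dates = sorted({r.date for r in random_dated_records})
        for cut in dates[:-1]:
            prefix_records = [r for r in random_dated_records if r.date <= cut]
            prefix = run_repository(prefix_records, cfg, seed=11)
            head = whole.frame.iloc[: len(prefix.frame)].reset_index(drop=True)
            pd.testing.assert_frame_equal(head, prefix.frame, check_exact=True)
            # and the grown run is exactly what update_repository returns
            out = update_repository(prefix, random_dated_records, cfg, seed=11)
            pd.testing.assert_frame_equal(out.frame, whole.frame, check_exact=True)


class TestRoundTrip:
    def test_csv_round_trip_is_lossless(self, tmp_path, random_dated_records):
        cfg = ProcedureConfig(alpha=0.05, variant="lord_pp")
        result = run_repository(random_dated_records, cfg, seed=2)
        path = tmp_path / "results.csv"
        result.to_csv(path)
        assert (tmp_path / "results.meta.json").exists()
        back = RepositoryResult.from_csv(path)
        assert list(back.frame["id"]) == list(result.frame["id"])
        assert list(back.frame["date"]) == list(result.frame["date"])
        assert np.array_equal(back.frame["R"].to_numpy(), result.frame["R"].to_numpy())
        # thresholds round-trip exactly at 17 significant digits
        assert np.array_equal(back.frame["alphai"].to_numpy(), result.frame["alphai"].to_numpy())
        assert back.metadata == result.metadata

    def test_update_works_from_reloaded_result(self, tmp_path):
        base = make_records([("2020-01-01", 0.001), ("2020-01-01", 0.8)])
        cfg = ProcedureConfig(alpha=0.05, variant="lord2")
        prev = run_repository(base, cfg, seed=4)
        path = tmp_path / "r.csv"
        prev.to_csv(path)
        reloaded = RepositoryResult.from_csv(path)
        grown = base + make_records([("2020-02-01", 0.3)], prefix="n")
        out = update_repository(reloaded, grown, cfg, seed=4)
        assert len(out.frame) == 3
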