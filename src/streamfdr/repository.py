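"""Apply online procedures to a (growing) repository of dated hypothesis tests.

A repository is a table of hypothesis records — unique identifier, calendar
date, p-value — that grows over time as new batches of tests are uploaded.
The online procedures need a single well-defined stream order, and for
methods requiring independent p-values the order within a same-date batch
must be random or based on independent information.  This module provides:

* :func:`order_stream` — date-ascending ordering with reproducible
  within-batch randomization.  Each batch's permutation is drawn from an
  RNG keyed by ``(seed, batch date)`` alone, so appending later batches can
  never reshuffle history.  Records carrying an explicit ``order`` value
  bypass randomization ("ordered using independent information").
* :func:`run_repository` — order the records and run a procedure over the
  resulting p-value stream.
* :func:`update_repository` — re-analyse a grown repository: thresholds and
  decisions for the new, later-dated records continue the same
  wealth/discovery state while every previously reported row is
  reproduced bit-for-bit (and verified to be).

Decisions are final: appending records dated on or before the last analysed
batch, or changing a recorded p-value, is an error — p-values are assumed
valid and finalized.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import (
    DuplicateIdError,
    ImmutabilityError,
    InvalidDateError,
    InvalidPValueError,
    OutOfOrderAppendError,
)
from .procedures import ProcedureConfig, run_procedure

__all__ = [
    "HypothesisRecord",
    "RepositoryResult",
    "order_stream",
    "run_repository",
    "update_repository",
    "read_records_csv",
    "records_from_frame",
]

logger = logging.getLogger(__name__)

_RESULT_COLUMNS = ["id", "date", "pval", "index", "alphai", "R"]


@dataclass(frozen=True)
class HypothesisRecord:
    """One hypothesis test: opaque id, ISO calendar date, p-value.

    ``order`` optionally fixes the record's rank within its date batch
    (independent information supplied by the user); when present for a
    batch it must be present, and unique, for every record of that batch.
    """

    id: str
    date: _dt.date
    pval: float
    order: float | None = None


@dataclass
class RepositoryResult:
    """Outcome of a repository analysis.

    ``frame`` has one row per record in stream order with columns
    ``id, date, pval, index, alphai, R`` (``index`` is the 1-based stream
    position, ``alphai`` the adjusted threshold, ``R`` the 0/1 decision).
    ``metadata`` records the procedure, level, seed and gamma kind needed
    to extend the analysis later.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> Path:
        """Write the result table plus a JSON metadata sidecar.

        Floats are written with 17 significant digits so they round-trip
        exactly; the sidecar lands next to the CSV as ``<stem>.meta.json``.
        """
        path = Path(path)
        self.frame.to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps(self.metadata, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_csv(cls, path) -> "RepositoryResult":
        path = Path(path)
        # round_trip parsing recovers the exact float64 written at 17 digits
        frame = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
        frame["date"] = pd.to_datetime(frame["date"], format="%Y-%m-%d").dt.date
        sidecar = path.with_suffix(".meta.json")
        metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(frame=frame, metadata=metadata)


def _parse_date(value, context: str = "") -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise InvalidDateError(f"unparseable date {value!r}{context}; expected YYYY-MM-DD") from exc


def records_from_frame(df: pd.DataFrame) -> list[HypothesisRecord]:
    """Build validated records from a DataFrame with columns id, date, pval[, order]."""
    missing = {"id", "date", "pval"} - set(df.columns)
    if missing:
        raise ValueError(f"input table is missing columns: {sorted(missing)}")
    has_order = "order" in df.columns
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):  # 1 is the header
        rid = str(getattr(row, "id"))
        date = _parse_date(getattr(row, "date"), context=f" in row {row_number}")
        pval = getattr(row, "pval")
        try:
            pval = float(pval)
        except (TypeError, ValueError):
            pval = float("nan")
        if not (0.0 <= pval <= 1.0):
            raise InvalidPValueError(
                f"p-value for id {rid!r} in row {row_number} is not in [0, 1]: {getattr(row, 'pval')!r}"
            )
        order = getattr(row, "order") if has_order else None
        if order is not None and (isinstance(order, float) and np.isnan(order)):
            order = None
        records.append(HypothesisRecord(id=rid, date=date, pval=pval, order=order))
    return records


def read_records_csv(path) -> list[HypothesisRecord]:
    """Read a ``id,date,pval[,order]`` CSV into validated records."""
    df = pd.read_csv(path, dtype={"id": str})
    return records_from_frame(df)


def _check_unique_ids(records) -> None:
    seen = set()
    for r in records:
        if r.id in seen:
            raise DuplicateIdError(f"duplicate hypothesis id: {r.id!r}")
        seen.add(r.id)


def _batch_rng(seed: int, date: _dt.date) -> np.random.Generator:
    # keyed by (seed, date) only: appending later batches never reshuffles
    # an earlier batch's permutation
    return np.random.default_rng(np.random.SeedSequence([int(seed), date.toordinal()]))


def order_stream(records, seed: int) -> list[HypothesisRecord]:
    """Order records by date; randomize (reproducibly) within each date batch.

    Within a batch the permutation is drawn from an RNG keyed by
    ``(seed, batch date)`` alone.  If any record of a batch carries an
    explicit ``order`` value, all of them must, and the batch is sorted by
    that value instead of being randomized.
    """
    records = list(records)
    for r in records:
        _parse_date(r.date)
        if not (0.0 <= float(r.pval) <= 1.0):
            raise InvalidPValueError(f"p-value for id {r.id!r} is not in [0, 1]: {r.pval!r}")
    _check_unique_ids(records)
    batches: dict[_dt.date, list[HypothesisRecord]] = {}
    for r in records:
        batches.setdefault(r.date, []).append(r)
    ordered: list[HypothesisRecord] = []
    for date in sorted(batches):
        batch = batches[date]
        has_order = [r.order is not None for r in batch]
        if any(has_order):
            if not all(has_order):
                raise ValueError(
                    f"batch {date.isoformat()}: explicit order must be given for all records or none"
                )
            keys = [r.order for r in batch]
            if len(set(keys)) != len(keys):
                raise ValueError(f"batch {date.isoformat()}: explicit order values must be unique")
            ordered.extend(sorted(batch, key=lambda r: r.order))
        else:
            perm = _batch_rng(seed, date).permutation(len(batch))
            ordered.extend(batch[i] for i in perm)
    return ordered


def run_repository(records, procedure: ProcedureConfig, seed: int) -> RepositoryResult:
    """Order a repository's records and run an online procedure over them.

    Returns one row per record in stream order, carrying both the original
    id and the stream index so results can be re-joined to the source
    table.
    """
    ordered = order_stream(records, seed)
    pvals = np.array([r.pval for r in ordered], dtype=float)
    table = run_procedure(pvals, procedure)
    frame = pd.DataFrame(
        {
            "id": [r.id for r in ordered],
            "date": [r.date for r in ordered],
            "pval": pvals,
            "index": np.arange(1, len(ordered) + 1),
            "alphai": table.alphai,
            "R": table.reject.astype(int),
        },
        columns=_RESULT_COLUMNS,
    )
    cum_disc = 0
    for date, grp in frame.groupby("date", sort=True):
        cum_disc += int(grp["R"].sum())
        logger.info(
            "batch %s: %d tests, %d discoveries to date", date, len(grp), cum_disc
        )
    metadata = {
        "procedure": procedure.variant,
        "alpha": procedure.alpha,
        "w0": procedure.w0,
        "gamma_kind": procedure.gamma_kind,
        "seed": int(seed),
        "package_version": __version__,
    }
    return RepositoryResult(frame=frame, metadata=metadata)


def update_repository(
    previous: RepositoryResult,
    all_records,
    procedure: ProcedureConfig,
    seed: int,
) -> RepositoryResult:
    """Re-analyse a grown repository, keeping every previous result fixed.

    ``all_records`` must contain every previously analysed record unchanged
    (same date and p-value) plus any number of new records, all dated
    strictly after the last analysed batch — decisions are final, and a
    same-date append would reopen a finalized batch.  The whole stream is
    recomputed from scratch and the prefix is verified bit-for-bit against
    ``previous`` before the extended result is returned; by per-batch
    seeding and prefix invariance of the procedures this check can only
    fail if the inputs or configuration were tampered with.
    """
    all_records = list(all_records)
    _check_unique_ids(all_records)
    prev = previous.frame
    meta = previous.metadata
    for key, value in (
        ("procedure", procedure.variant),
        ("alpha", procedure.alpha),
        ("w0", procedure.w0),
        ("gamma_kind", procedure.gamma_kind),
        ("seed", int(seed)),
    ):
        if key in meta and meta[key] != value:
            raise ValueError(
                f"update must reuse the previous run's configuration: {key} was {meta[key]!r}, got {value!r}"
            )
    by_id = {r.id: r for r in all_records}
    missing = [rid for rid in prev["id"] if rid not in by_id]
    if missing:
        raise ImmutabilityError(f"previously analysed ids missing from the update: {missing[:5]}")
    for rid, date, pval in zip(prev["id"], prev["date"], prev["pval"]):
        r = by_id[rid]
        if _parse_date(r.date) != _parse_date(date) or float(r.pval) != float(pval):
            raise ImmutabilityError(
                f"record {rid!r} changed between runs; analysed p-values are final"
            )
    if len(prev):
        last_date = max(_parse_date(d) for d in prev["date"])
        prev_ids = set(prev["id"])
        for r in all_records:
            if r.id not in prev_ids and r.date <= last_date:
                raise OutOfOrderAppendError(
                    f"record {r.id!r} dated {r.date.isoformat()} does not postdate the last "
                    f"analysed batch ({last_date.isoformat()}); assign new batches a later date"
                )
    full = run_repository(all_records, procedure, seed)
    k = len(prev)
    head = full.frame.iloc[:k]
    same = (
        list(head["id"]) == list(prev["id"])
        and [_parse_date(d) for d in head["date"]] == [_parse_date(d) for d in prev["date"]]
        and np.array_equal(head["pval"].to_numpy(), prev["pval"].to_numpy(dtype=float))
        and np.array_equal(head["index"].to_numpy(), prev["index"].to_numpy())
        and np.array_equal(head["alphai"].to_numpy(), prev["alphai"].to_numpy(dtype=float))
        and np.array_equal(head["R"].to_numpy(), prev["R"].to_numpy())
    )
    if not same:
        raise RuntimeError(
            "recomputed prefix diverged from the stored results; refusing to overwrite history"
        )
    return full
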