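import datetime as dt

import numpy as np
import pytest

from streamfdr import HypothesisRecord, SpendingSequence


@pytest.fixture
def halving_gamma() -> SpendingSequence:
    """The (0.5, 0.25, 0.125, ...) sequence used in the worked recursions."""
    return SpendingSequence(values=0.5 ** np.arange(1, 13), kind="user")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190314)


def make_records(dates_and_pvals, prefix="h"):
    """Build HypothesisRecords from (iso-date, pval) pairs with generated ids."""
    return [
        HypothesisRecord(id=f"{prefix}{i}", date=dt.date.fromisoformat(d), pval=p)
        for i, (d, p) in enumerate(dates_and_pvals)
    ]


@pytest.fixture
def random_dated_records(rng):
    """60 records over 5 consecutive dates with a mix of null and small p-values."""
    dates = [f"2018-06-{day:02d}" for day in range(1, 6)]
    pairs = []
    for d in dates:
        for _ in range(12):
            p = rng.random() if rng.random() > 0.3 else rng.random() * 1e-3
            pairs.append((d, p))
    return make_records(pairs)
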