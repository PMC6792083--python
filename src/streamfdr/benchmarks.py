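"""Offline comparison procedures: BH, BY and fixed-threshold testing.

These require the whole p-value family at once, so they cannot be applied
to a growing repository without re-opening past decisions; they serve as
benchmarks for the online rules.  BH is the usual step-up procedure for
independent (or positively dependent) p-values; BY is BH run at level
``alpha / H(m)`` with ``H(m)`` the m-th harmonic number, valid under
arbitrary dependence.  Fixed-threshold testing is the ad hoc practice of
many databases (e.g. declaring phenodeviants at P < 0.0001).
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidPValueError
from .procedures import DecisionTable, _validate_pvals

__all__ = ["bh", "by", "fixed_threshold"]


def bh(pvals, alpha: float = 0.05) -> DecisionTable:
    """Benjamini–Hochberg step-up procedure at level ``alpha``.

    Rejects the ``k*`` smallest p-values where
    ``k* = max{k : p_(k) <= k * alpha / m}`` (0 if the set is empty).  The
    rejection region is the single cutoff ``k* * alpha / m``, which is
    stored as the (common) adjusted threshold ``alphai``; tied p-values
    share a fate by construction.  The comparison is non-strict.
    """
    p = _validate_pvals(pvals)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    m = p.size
    if m == 0:
        return DecisionTable(pvals=p, alphai=np.empty(0), reject=np.zeros(0, dtype=bool))
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = np.arange(1, m + 1)
    passed = np.nonzero(sorted_p <= k * alpha / m)[0]
    kstar = int(passed[-1] + 1) if passed.size else 0
    cutoff = kstar * alpha / m
    reject = p <= cutoff
    alphai = np.full(m, cutoff)
    return DecisionTable(pvals=p, alphai=alphai, reject=reject)


def by(pvals, alpha: float = 0.05) -> DecisionTable:
    """Benjamini–Yekutieli: BH at level ``alpha / H(m)``.

    Valid under arbitrary dependence between the p-values; its rejection
    set is always a subset of BH's at the same nominal level.
    """
    p = _validate_pvals(pvals)
    m = p.size
    if m == 0:
        return DecisionTable(pvals=p, alphai=np.empty(0), reject=np.zeros(0, dtype=bool))
    harmonic = float(np.sum(1.0 / np.arange(1, m + 1)))
    return bh(p, alpha / harmonic)


def fixed_threshold(pvals, threshold: float) -> DecisionTable:
    """Reject every hypothesis with ``p < threshold`` (strict inequality).

    Mirrors the database convention of declaring significance strictly
    below a fixed cutoff, so — unlike the online procedures — the decision
    is ``p < alphai``, not ``p <= alphai``.  Provides no FDR guarantee and
    does not adapt to the data; included purely as a benchmark.
    """
    p = _validate_pvals(pvals)
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold!r}")
    alphai = np.full(p.size, float(threshold))
    return DecisionTable(pvals=p, alphai=alphai, reject=p < threshold)
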