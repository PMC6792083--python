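"""Sequential adjusted-threshold procedures for online FDR control.

For a stream of null hypotheses ``H_1, H_2, ...`` with p-values
``p_1, p_2, ...`` arriving one at a time, each procedure emits an adjusted
significance threshold ``alpha_i`` computed only from the past (previous
thresholds and decisions, never from ``p_i`` or the future) and rejects
``H_i`` when ``p_i <= alpha_i``.  Writing ``tau_1 < tau_2 < ...`` for the
discovery (rejection) times, ``D(i)`` for the number of discoveries among
the first ``i`` tests, ``gamma`` for a spending sequence, ``w0`` for the
initial alpha-wealth and ``b0 = alpha - w0`` for the payout earned at each
discovery, the implemented rules are:

``alpha_spending``
    ``alpha_i = alpha * gamma_i`` — data-independent Bonferroni-like
    spending; controls FWER (hence FDR) under arbitrary dependence.
``lond`` / ``lond_dep``
    ``alpha_i = alpha * gamma_i * (D(i-1) + 1)`` — significance Levels
    based On the Number of Discoveries.  The dependent variant first
    divides ``gamma`` by the harmonic numbers, restoring validity under
    arbitrary dependence.
``lord1``
    ``alpha_i = gamma_i * w0`` before the first discovery, then
    ``gamma_{i - tau(i)} * b0`` where ``tau(i)`` is the most recent
    discovery time.  Never exceeds LORD 2.
``lord2`` / ``lord_dep``
    ``alpha_i = gamma_i * w0 + b0 * sum_{j: tau_j < i} gamma_{i - tau_j}``
    — significance Levels based On Recent Discovery.  ``lord_dep`` runs the
    same recursion with the ``dependent_default`` spending sequence.
``lord_pp`` (LORD++)
    ``alpha_i = gamma_i * w0 + (alpha - w0) * gamma_{i - tau_1}
    + alpha * sum_{j>=2} gamma_{i - tau_j}`` — a refinement of LORD 2 with
    thresholds that are never smaller.
``lord3``
    ``alpha_i = gamma_{i - tau(i)} * W(tau(i))`` with wealth
    ``W(t) = W(t-1) - alpha_t + b0 * R_t`` and ``W(0) = w0``.  Its FDR
    control has been demonstrated empirically, not proven; prefer LORD 2
    or LORD++ when a guarantee is required.

LOND, LORD 1/2/3, LORD++ and alpha-spending control the FDR at level
``alpha`` for independent p-values; alpha-spending, lond (dependent) and
lord_dep remain valid under dependence.  All rules are *online*: extending
a stream never changes earlier thresholds or decisions, and processing a
stream step-by-step with :func:`step` reproduces the batch functions
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidPValueError, SequenceTooShortError
from .sequences import (
    DEPENDENT_DEFAULT,
    LORD_DEFAULT,
    SpendingSequence,
    default_gamma,
    harmonic_correction,
    validate_gamma,
)

__all__ = [
    "VARIANTS",
    "LORD_VARIANTS",
    "ProcedureConfig",
    "WealthState",
    "DecisionTable",
    "StepResult",
    "step",
    "run_procedure",
    "lond",
    "lord",
    "alpha_spending",
]

VARIANTS = (
    "lond",
    "lond_dep",
    "lord1",
    "lord2",
    "lord3",
    "lord_pp",
    "lord_dep",
    "alpha_spending",
)
LORD_VARIANTS = frozenset({"lord1", "lord2", "lord3", "lord_pp", "lord_dep"})


@dataclass
class ProcedureConfig:
    """Configuration of one online procedure.

    Parameters
    ----------
    alpha
        Target FDR level, in (0, 1).
    variant
        One of :data:`VARIANTS`.
    w0
        Initial alpha-wealth for the LORD family, in (0, alpha).
        Defaults to ``alpha / 10``.  The payout per discovery is
        ``b0 = alpha - w0``.
    gamma
        Spending sequence.  ``None`` selects the default for the variant
        (``dependent_default`` for ``lord_dep``, ``lord_default``
        otherwise).  A user sequence shorter than the stream is an error —
        it is never zero-padded, because zero thresholds silently kill
        power.  Longer sequences are truncated at use time.
    """

    alpha: float = 0.05
    variant: str = "lord_pp"
    w0: float | None = None
    gamma: SpendingSequence | None = None
    _gamma_cache: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.w0 is None:
            self.w0 = self.alpha / 10.0
        if not (0.0 < self.w0 < self.alpha):
            raise ValueError(f"w0 must lie in (0, alpha), got w0={self.w0!r}, alpha={self.alpha!r}")
        if self.gamma is not None:
            validate_gamma(self.gamma)

    @property
    def b0(self) -> float:
        """Alpha-wealth earned back at each discovery."""
        return self.alpha - self.w0

    @property
    def gamma_kind(self) -> str:
        if self.gamma is not None:
            return self.gamma.kind
        return DEPENDENT_DEFAULT if self.variant == "lord_dep" else LORD_DEFAULT

    def gamma_values(self, n: int) -> np.ndarray:
        """First ``n`` spending weights, with the variant's corrections applied.

        Default sequences are extended on demand (their closed forms do not
        depend on the requested length, so extension never perturbs earlier
        weights); user sequences that do not cover ``n`` raise
        :class:`SequenceTooShortError`.
        """
        if self.gamma is not None:
            if len(self.gamma) < n:
                raise SequenceTooShortError(
                    f"spending sequence of length {len(self.gamma)} does not cover a stream of {n} tests"
                )
            base = self.gamma
            if self.variant == "lond_dep":
                base = harmonic_correction(base)
            return base.values[:n]
        if self._gamma_cache is None or self._gamma_cache.size < n:
            m = max(n, 64)
            seq = default_gamma(m, self.gamma_kind)
            if self.variant == "lond_dep":
                seq = harmonic_correction(seq)
            self._gamma_cache = seq.values
        return self._gamma_cache[:n]


@dataclass(frozen=True)
class WealthState:
    """Running state of an online procedure after ``t`` tests.

    ``wealth`` is the current alpha-wealth ``W(t)`` for the LORD family and
    ``None`` for rules without a wealth account (LOND, alpha-spending).
    ``wealth_last_discovery`` is ``W(tau)`` at the most recent discovery
    (``W(0) = w0`` before any), which is what the LORD 3 threshold reads.
    """

    t: int = 0
    wealth: float | None = None
    discoveries: tuple[int, ...] = ()
    wealth_last_discovery: float | None = None

    @property
    def num_discoveries(self) -> int:
        return len(self.discoveries)


class StepResult(NamedTuple):
    alphai: float
    reject: bool
    state: WealthState


@dataclass(frozen=True)
class DecisionTable:
    """Per-hypothesis output of a procedure run.

    ``index`` is the 1-based test order, ``alphai`` the adjusted
    significance thresholds, and ``reject`` the decisions
    ``R_i = 1{p_i <= alpha_i}`` (the fixed-threshold benchmark, which uses
    a strict ``<`` by database convention, is the one exception).
    """

    pvals: np.ndarray
    alphai: np.ndarray
    reject: np.ndarray

    @property
    def index(self) -> np.ndarray:
        return np.arange(1, self.pvals.size + 1)

    @property
    def num_rejections(self) -> int:
        return int(np.count_nonzero(self.reject))

    @property
    def rejections(self) -> np.ndarray:
        """1-based indices of the rejected hypotheses."""
        return np.nonzero(self.reject)[0] + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.index,
                "pval": self.pvals,
                "alphai": self.alphai,
                "R": self.reject.astype(int),
            }
        )


def _validate_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise InvalidPValueError("p-values must form a 1-d sequence")
    bad = ~((p >= 0.0) & (p <= 1.0))  # catches NaN as well
    if np.any(bad):
        i = int(np.nonzero(bad)[0][0])
        raise InvalidPValueError(f"p-value at position {i + 1} is not in [0, 1]: {p[i]!r}")
    return p


def _threshold(
    variant: str,
    alpha: float,
    w0: float,
    b0: float,
    g: Sequence[float],
    t: int,
    disc: Sequence[int],
    wealth_last: float,
) -> float:
    """Adjusted threshold alpha_t given the history through test t-1.

    ``g`` is 0-based; the gap index convention is 1-based in test counts,
    so the test immediately after a discovery at tau reads ``g[t-tau-1]``
    with gap 1.  Shared by the streaming and batch paths so the two are
    bit-identical by construction.
    """
    if variant == "alpha_spending":
        return alpha * g[t - 1]
    if variant == "lond" or variant == "lond_dep":
        return alpha * g[t - 1] * (len(disc) + 1)
    if variant == "lord1":
        if not disc:
            return w0 * g[t - 1]
        return b0 * g[t - disc[-1] - 1]
    if variant == "lord3":
        gap = t - (disc[-1] if disc else 0)
        return wealth_last * g[gap - 1]
    if variant == "lord2" or variant == "lord_dep":
        a = w0 * g[t - 1]
        for tau in disc:
            a += b0 * g[t - tau - 1]
        return a
    # lord_pp: payout alpha - w0 for the first discovery, alpha afterwards
    a = w0 * g[t - 1]
    if disc:
        a += (alpha - w0) * g[t - disc[0] - 1]
        for tau in disc[1:]:
            a += alpha * g[t - tau - 1]
    return a


def _payout(variant: str, alpha: float, b0: float, n_disc_before: int) -> float:
    if variant == "lord_pp" and n_disc_before >= 1:
        return alpha
    return b0


def fresh_state(config: ProcedureConfig) -> WealthState:
    """Initial :class:`WealthState` consistent with ``config``."""
    if config.variant in LORD_VARIANTS:
        return WealthState(t=0, wealth=config.w0, discoveries=(), wealth_last_discovery=config.w0)
    return WealthState(t=0, wealth=None, discoveries=(), wealth_last_discovery=None)


def step(state: WealthState, p: float, config: ProcedureConfig) -> StepResult:
    """Process one p-value, returning the threshold, decision and new state.

    The threshold is a function of the state alone — it is fixed before
    ``p`` is looked at — so a stream can be processed as its p-values
    arrive, with no knowledge of the future.  Repeated application
    reproduces the batch functions exactly.
    """
    pf = float(p) if p is not None else np.nan
    if not (0.0 <= pf <= 1.0):
        raise InvalidPValueError(f"p-value must lie in [0, 1], got {p!r}")
    t = state.t + 1
    g = config.gamma_values(t)
    w0, alpha, b0 = config.w0, config.alpha, config.b0
    wl = state.wealth_last_discovery if state.wealth_last_discovery is not None else 0.0
    a = _threshold(config.variant, alpha, w0, b0, g, t, state.discoveries, wl)
    r = pf <= a
    if config.variant in LORD_VARIANTS:
        wealth = state.wealth - a
        if r:
            wealth += _payout(config.variant, alpha, b0, state.num_discoveries)
        new = WealthState(
            t=t,
            wealth=wealth,
            discoveries=state.discoveries + (t,) if r else state.discoveries,
            wealth_last_discovery=wealth if r else state.wealth_last_discovery,
        )
    else:
        new = WealthState(
            t=t,
            wealth=None,
            discoveries=state.discoveries + (t,) if r else state.discoveries,
            wealth_last_discovery=None,
        )
    return StepResult(alphai=a, reject=bool(r), state=new)


def run_procedure(pvals, config: ProcedureConfig) -> DecisionTable:
    """Run a procedure over a whole stream of p-values.

    Equivalent to folding :func:`step` over the stream; the loop below
    keeps the history in plain lists for speed but calls the same
    :func:`_threshold` formula, so the two paths agree bit-for-bit.
    Cost is O(n) for LOND/LORD1/LORD3/alpha-spending and O(n * D) for
    LORD2/LORD++ (direct summation over past discoveries).
    """
    p = _validate_pvals(pvals)
    n = p.size
    variant = config.variant
    alphai = np.empty(n)
    reject = np.zeros(n, dtype=bool)
    if n == 0:
        return DecisionTable(pvals=p, alphai=alphai, reject=reject)
    g = config.gamma_values(n).tolist()
    alpha, w0, b0 = config.alpha, config.w0, config.b0

    if variant == "alpha_spending":
        alphai[:] = alpha * np.asarray(g)
        reject[:] = p <= alphai
        return DecisionTable(pvals=p, alphai=alphai, reject=reject)

    disc: list[int] = []
    wealth = w0 if variant in LORD_VARIANTS else 0.0
    wealth_last = wealth
    is_lord = variant in LORD_VARIANTS
    for t in range(1, n + 1):
        a = _threshold(variant, alpha, w0, b0, g, t, disc, wealth_last)
        r = p[t - 1] <= a
        if is_lord:
            wealth -= a
            if r:
                wealth += _payout(variant, alpha, b0, len(disc))
                wealth_last = wealth
        if r:
            disc.append(t)
        alphai[t - 1] = a
        reject[t - 1] = r
    return DecisionTable(pvals=p, alphai=alphai, reject=reject)


def lond(
    pvals,
    alpha: float = 0.05,
    gamma: SpendingSequence | None = None,
    dependent: bool = False,
) -> DecisionTable:
    """LOND: thresholds scale the spending weights by D(i-1) + 1.

    With ``dependent=True`` the spending sequence is first divided by the
    harmonic numbers, which restores FDR control under arbitrarily
    dependent p-values at a substantial cost in power.  For independent
    p-values LOND's thresholds dominate plain alpha-spending with the same
    sequence, so it never has lower power.
    """
    cfg = ProcedureConfig(alpha=alpha, variant="lond_dep" if dependent else "lond", gamma=gamma)
    return run_procedure(pvals, cfg)


def lord(pvals, config: ProcedureConfig) -> DecisionTable:
    """Run a LORD-family procedure (lord1, lord2, lord3, lord_pp, lord_dep)."""
    if config.variant not in LORD_VARIANTS:
        raise ValueError(f"lord() requires a LORD variant, got {config.variant!r}")
    return run_procedure(pvals, config)


def alpha_spending(
    pvals, alpha: float = 0.05, gamma: SpendingSequence | None = None
) -> DecisionTable:
    """Bonferroni-like spending: ``alpha_i = alpha * gamma_i``, data-independent.

    Controls the family-wise error rate — hence the FDR — under arbitrary
    dependence, at the price of monotonically vanishing thresholds.
    """
    cfg = ProcedureConfig(alpha=alpha, variant="alpha_spending", gamma=gamma)
    return run_procedure(pvals, cfg)
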