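"""Spending sequences: the weights gamma that meter alpha-wealth over a stream.

Every online procedure in this package spreads its error budget over future
tests according to a sequence of non-negative weights ``gamma_1, gamma_2, ...``
with ``sum(gamma_j) <= 1``.  Two default families are provided:

``lord_default``
    ``gamma_j = c * log(max(j, 2)) / (j * exp(sqrt(log j)))`` — the slowly
    decaying sequence conventionally paired with the LORD family of
    generalized alpha-investing rules for independent p-values.

``dependent_default``
    ``gamma_j = c~ / (j * log(max(j, 2))**3)`` — a summable-enough sequence
    used by the LORD variant that remains valid under arbitrary dependence.

The normalizing constants ``c`` and ``c~`` make the corresponding infinite
series sum to one.  They are computed numerically on first use (partial sum
plus a closed-form integral remainder, truncation error below 1e-12) and
cached for the lifetime of the process, so repeated calls are bit-identical.

User-supplied sequences are first class: any published sequence can be
injected via :class:`SpendingSequence` and is validated, never repaired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidSequenceError

__all__ = [
    "LORD_DEFAULT",
    "DEPENDENT_DEFAULT",
    "USER",
    "SpendingSequence",
    "default_gamma",
    "validate_gamma",
    "harmonic_correction",
    "series_constant",
]

logger = logging.getLogger(__name__)

LORD_DEFAULT = "lord_default"
DEPENDENT_DEFAULT = "dependent_default"
USER = "user"

_SUM_TOL = 1e-9

#: number of terms summed directly before switching to the integral remainder
_N_DIRECT = 4_000_000

_constant_cache: dict[str, float] = {}


@dataclass(frozen=True)
class SpendingSequence:
    """An ordered sequence of non-negative spending weights.

    Parameters
    ----------
    values
        One weight per future test position.  Stored as an immutable
        float64 array.
    kind
        ``"lord_default"``, ``"dependent_default"`` or ``"user"``.
    """

    values: np.ndarray
    kind: str = USER

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidSequenceError("spending sequence must be a non-empty 1-d array")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)


def _lord_terms(j: np.ndarray) -> np.ndarray:
    # numerator uses log(max(j,2)); denominator uses the raw log j (zero at j=1)
    return np.log(np.maximum(j, 2.0)) / (j * np.exp(np.sqrt(np.log(j))))


def _dependent_terms(j: np.ndarray) -> np.ndarray:
    return 1.0 / (j * np.log(np.maximum(j, 2.0)) ** 3)


def _lord_tail(x: float) -> float:
    # int_x^inf log t / (t e^sqrt(log t)) dt  with u = sqrt(log t):
    # = 2 int u^3 e^-u du = 2 e^-u (u^3 + 3u^2 + 6u + 6)
    u = math.sqrt(math.log(x))
    return 2.0 * math.exp(-u) * (u**3 + 3.0 * u**2 + 6.0 * u + 6.0)


def _dependent_tail(x: float) -> float:
    # int_x^inf dt / (t log^3 t) = 1 / (2 log^2 x)
    return 1.0 / (2.0 * math.log(x) ** 2)


def series_constant(kind: str) -> float:
    """Normalizing constant for a default sequence kind.

    Computed as 1 / S where S is the infinite series sum, evaluated as a
    direct partial sum over the first ``4e6`` terms plus the closed-form
    integral of the term function from ``N + 1/2`` to infinity (the midpoint
    Euler–Maclaurin remainder).  The truncation error of this scheme is
    below 1e-12, far inside the float64 accumulation noise.  The result is
    cached, so every later call is bit-identical.
    """
    if kind in _constant_cache:
        return _constant_cache[kind]
    if kind == LORD_DEFAULT:
        terms, tail = _lord_terms, _lord_tail
    elif kind == DEPENDENT_DEFAULT:
        terms, tail = _dependent_terms, _dependent_tail
    else:
        raise ValueError(f"unknown default sequence kind: {kind!r}")

    total = 0.0
    chunk = 1_000_000
    for start in range(1, _N_DIRECT + 1, chunk):
        j = np.arange(start, min(start + chunk, _N_DIRECT + 1), dtype=float)
        total += float(np.sum(terms(j)))
    total += tail(_N_DIRECT + 0.5)
    const = 1.0 / total
    _constant_cache[kind] = const
    logger.info("normalizing constant for %s computed: %.15g (series sum %.15g)", kind, const, total)
    return const


def default_gamma(n: int, kind: str = LORD_DEFAULT) -> SpendingSequence:
    """Evaluate a default spending sequence at positions 1..n.

    Parameters
    ----------
    n
        Number of positions; must be >= 1.
    kind
        ``"lord_default"`` or ``"dependent_default"``.

    Returns
    -------
    SpendingSequence
        The first ``n`` weights of the chosen infinite sequence.  Because
        each weight is a fixed closed form, requesting a longer prefix never
        changes earlier values.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    c = series_constant(kind)  # raises for unknown kind
    j = np.arange(1, n + 1, dtype=float)
    vals = c * (_lord_terms(j) if kind == LORD_DEFAULT else _dependent_terms(j))
    return SpendingSequence(values=vals, kind=kind)


def validate_gamma(seq: SpendingSequence) -> SpendingSequence:
    """Check a spending sequence's invariants and return it unchanged.

    A sequence is valid when every element is non-negative and no partial
    sum exceeds 1 (tolerance 1e-9).  Invalid sequences are rejected, never
    truncated or repaired.
    """
    vals = seq.values
    if np.any(~np.isfinite(vals)):
        raise InvalidSequenceError("spending sequence contains non-finite values")
    neg = np.nonzero(vals < 0)[0]
    if neg.size:
        raise InvalidSequenceError(
            f"spending sequence has a negative element at position {neg[0] + 1}: {vals[neg[0]]!r}"
        )
    partial = np.cumsum(vals)
    over = np.nonzero(partial > 1.0 + _SUM_TOL)[0]
    if over.size:
        raise InvalidSequenceError(
            f"partial sum exceeds 1 at position {over[0] + 1}: {partial[over[0]]!r}"
        )
    if seq.kind == LORD_DEFAULT and np.any(np.diff(vals) > 0):
        raise InvalidSequenceError("lord_default sequences must be non-increasing")
    return seq


def harmonic_correction(seq: SpendingSequence) -> SpendingSequence:
    """Divide each weight by the harmonic number of its position.

    Returns ``gamma_j / H(j)`` with ``H(j) = sum_{k<=j} 1/k``.  This is the
    correction that makes a number-of-discoveries rule (LOND) valid under
    arbitrarily dependent p-values, at a cost in power: the corrected
    weights are elementwise no larger than the originals.
    """
    validate_gamma(seq)
    h = np.cumsum(1.0 / np.arange(1, len(seq) + 1, dtype=float))
    return SpendingSequence(values=seq.values / h, kind=USER)
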