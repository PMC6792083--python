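"""Exception hierarchy for streamfdr.

All errors derive from :class:`StreamFDRError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from :class:`ValueError` for compatibility with generic validation handling.
"""


class StreamFDRError(Exception):
    """Base class for all streamfdr errors."""


class InvalidSequenceError(StreamFDRError, ValueError):
    """A spending sequence violates non-negativity or the unit-sum budget."""


class SequenceTooShortError(StreamFDRError, ValueError):
    """A user-supplied spending sequence does not cover the stream length."""


class InvalidPValueError(StreamFDRError, ValueError):
    """A p-value is missing, non-finite, or outside [0, 1]."""


class DuplicateIdError(StreamFDRError, ValueError):
    """Two hypothesis records share an identifier."""


class InvalidDateError(StreamFDRError, ValueError):
    """A hypothesis record carries an unparseable date."""


class OutOfOrderAppendError(StreamFDRError, ValueError):
    """An appended record is dated on or before the last finalized batch."""


class ImmutabilityError(StreamFDRError, ValueError):
    """A previously analysed record changed between repository runs."""
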