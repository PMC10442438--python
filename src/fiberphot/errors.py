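"""Exception hierarchy.

All errors raised by the library derive from :class:`FiberphotError`, so
callers can catch one base class. Subclasses also derive from ``ValueError``
to play well with generic validation code.
"""


class FiberphotError(Exception):
    """Base class for all fiberphot errors."""


class ParameterError(FiberphotError, ValueError):
    """A parameter value is outside its admissible range."""


class DataError(FiberphotError, ValueError):
    """Input data violates a structural precondition (e.g. F <= 0)."""


class AlignmentError(FiberphotError, ValueError):
    """Two inputs that must share a timebase do not."""


class DegenerateFitError(FiberphotError, ValueError):
    """A fit cannot be computed (e.g. zero-variance regressor)."""


class ProtocolError(FiberphotError, ValueError):
    """An electrophysiology sweep set does not match its declared protocol."""
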