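"""Exception hierarchy shared by the model, I/O, core and service layers.

The service layer maps these onto HTTP statuses: :class:`NotFoundError`
becomes 404, :class:`ValidationError` becomes 400 except for mapping-column
problems (which the automation contract files under 404), and anything else
becomes 500.
"""


class CopycatError(Exception):
    """Base class for all errors raised by this package."""


class NotFoundError(CopycatError):
    """A network, view, column or node addressed by the caller does not exist."""


class ValidationError(CopycatError):
    """Input violates a structural precondition (duplicate ids, kind mismatch...)."""


class ColumnKindError(ValidationError):
    """The two mapping columns exist but are not both string- or both
    integer-typed. The automation contract files this under 404 together
    with absent columns."""


class FormatError(CopycatError):
    """A file could not be parsed as the claimed format."""
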