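"""Exception hierarchy.

All package errors derive from :class:`VitDSupplyError` so callers can
catch broadly; the three subfamilies map onto distinct CLI exit codes
(I/O and file-format problems, data validation, configuration).
"""


class VitDSupplyError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VitDSupplyError):
    """An input file does not conform to the expected dialect/schema."""


class ValidationError(VitDSupplyError):
    """Input data violates an invariant (negative supply, bad fraction...)."""


class DuplicateKeyError(ValidationError):
    """A key that must be unique appears more than once."""


class NotFoundError(VitDSupplyError):
    """A requested country/year/commodity is absent (distinct from zero)."""


class ConfigurationError(VitDSupplyError):
    """Inconsistent configuration (conflicting mapping rows, bad policy...)."""
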