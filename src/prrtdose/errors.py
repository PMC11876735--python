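"""Exception types shared across the package."""


class ConfigurationError(Exception):
    """Inconsistent or incomplete configuration (missing table entry, bad flag)."""


class ConservationError(ValueError):
    """Source organ activity exceeds the whole-body budget.

    Raised instead of clipping: it signals inconsistent quantification
    upstream, which must be fixed, not hidden.
    """


class FittingError(RuntimeError):
    """No candidate kinetic model could be fitted to the data."""
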