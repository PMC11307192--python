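"""Exception hierarchy shared across the package."""


class CriticalHRError(Exception):
    """Base class for all package errors."""


class SchemaError(CriticalHRError, ValueError):
    """Input file or table does not match the expected schema."""


class ParseError(CriticalHRError, ValueError):
    """A cell could not be parsed; message carries the row number."""


class FitError(CriticalHRError, ValueError):
    """Regression cannot be performed (too few points, singular design)."""


class DataValidationError(CriticalHRError, ValueError):
    """A domain invariant is violated (non-monotone time, bad range...)."""


class ConfigError(CriticalHRError, ValueError):
    """Run or simulation configuration is invalid."""
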