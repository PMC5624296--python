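"""Exception hierarchy. All package errors derive from :class:`HgtEnrichError`."""


class HgtEnrichError(Exception):
    """Base class for all hgtenrich errors."""


class ConfigError(HgtEnrichError, ValueError):
    """An invalid configuration field; the message names the field."""


class InputError(HgtEnrichError, ValueError):
    """Malformed or inconsistent input data (files or in-memory tables)."""


class DomainError(HgtEnrichError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class InsufficientDataError(HgtEnrichError, ValueError):
    """Too few data points to perform a fit or test."""


class DegenerateDataError(HgtEnrichError, ValueError):
    """Input with no usable variation (all-zero weights, collinear design, ...)."""
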