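"""Exception hierarchy for the ICISS pipeline."""


class IcissError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IcissError):
    """A registry file does not conform to the expected column layout."""


class IntegrityError(IcissError):
    """Data violate an internal consistency rule (e.g. duplicate ids,
    a 24-hour death recorded as a 30-day survivor)."""


class ValidationError(IcissError):
    """An argument or configuration object violates its contract."""


class DegenerateMetricError(IcissError):
    """A performance metric is undefined on the given data
    (single-class outcomes, constant predictions, ...)."""
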