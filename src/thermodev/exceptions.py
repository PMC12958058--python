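"""Exception hierarchy.

All package errors derive from :class:`ThermodevError` so callers can catch
one base class; subclasses distinguish configuration problems (bad column
mapping), data validation failures (bad rows, with line numbers), model-fit
failures (singular designs), and refusals (a model exists but is not
trustworthy enough to invert, or the requested condition is outside the
validated range).
"""


class ThermodevError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ThermodevError):
    """A required column or configuration key is missing or malformed."""


class ValidationError(ThermodevError, ValueError):
    """Input data violates a documented invariant.

    Where the offending input came from a file, the message names the
    1-based line number(s) of the rejected row(s).
    """


class FitError(ThermodevError, ValueError):
    """A model cannot be fitted (too few points, singular design, bad sign)."""


class CoverageError(ThermodevError, ValueError):
    """A temperature record does not cover the requested interval or cannot
    accumulate the required degree-hours; the message states the shortfall."""


class UnreliableModelError(ThermodevError, ValueError):
    """Refusal to invert a model whose fit quality is below the reliability
    threshold (e.g. pupal weight at low temperature)."""
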