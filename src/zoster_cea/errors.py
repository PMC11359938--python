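"""Exception hierarchy for the zoster-cea model."""


class ZosterCeaError(Exception):
    """Base class for all package-specific errors."""


class ParameterValidationError(ZosterCeaError, ValueError):
    """A parameter set violates one or more structural invariants.

    Carries the full list of :class:`~zoster_cea.params.Violation` objects so
    callers can report every problem at once instead of fixing them one by one.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations)
        super().__init__(f"invalid parameter set: {msg}")


class ConfigurationError(ZosterCeaError, ValueError):
    """A config file, dotted path, or distribution spec is malformed."""


class FittingError(ZosterCeaError, ValueError):
    """Efficacy-curve fitting received degenerate anchor data."""
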