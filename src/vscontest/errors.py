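"""Exception hierarchy for the screening pipeline."""


class VSContestError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VSContestError):
    """A configuration field is missing, malformed or out of range."""


class InputError(VSContestError):
    """An input table or argument violates a documented precondition."""


class GenerationError(VSContestError):
    """A synthetic-data request cannot be satisfied (e.g. not enough actives)."""


class ScreeningError(VSContestError):
    """A plate cannot be screened (e.g. too few compounds for plate statistics)."""


class FitError(VSContestError):
    """A dose-response fit cannot be attempted on the given data."""
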