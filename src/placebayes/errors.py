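"""Exception hierarchy for the placebayes pipeline."""


class PlacebayesError(Exception):
    """Base class for all placebayes errors."""


class ParameterError(PlacebayesError, ValueError):
    """An argument violates a precondition (non-positive scale, bad enum, ...)."""


class InsufficientDataError(PlacebayesError, ValueError):
    """Too few observations for the requested operation."""


class MissingCellError(PlacebayesError, KeyError):
    """A subject lacks trials in a required phase x condition cell."""

    def __init__(self, subject_id, phase: str, condition: str):
        self.subject_id = subject_id
        self.phase = phase
        self.condition = condition
        super().__init__(
            f"subject {subject_id!r} has no trials in cell "
            f"(phase={phase!r}, condition={condition!r})"
        )


class InputError(PlacebayesError, ValueError):
    """Malformed input table or file."""
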