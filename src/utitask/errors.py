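"""Exception hierarchy shared across the toolkit."""


class UtitaskError(Exception):
    """Base class for all toolkit errors."""


class FormatError(UtitaskError):
    """A delimited-text input does not match the documented schema."""


class DegenerateTrialError(UtitaskError):
    """A trial's geometry does not support the requested operation
    (zero extent, zero path length, coincident endpoints, ...)."""

    def __init__(self, message: str, participant_id: str = "", trial_id: str = ""):
        super().__init__(message)
        self.participant_id = participant_id
        self.trial_id = trial_id


class ModelError(UtitaskError):
    """A statistical model could not be estimated (non-convergence,
    separation, undefined variance)."""


class ConfigError(UtitaskError):
    """A configuration object violates its invariants."""
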