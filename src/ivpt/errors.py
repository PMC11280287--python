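"""Exception hierarchy for the IVPT pipeline.

Every stage raises a subclass of :class:`IVPTError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class IVPTError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(IVPTError):
    """A CSV/YAML input does not match the expected schema."""


class ValidationError(IVPTError):
    """A parsed value violates a physical or structural invariant."""


class FitError(IVPTError):
    """Steady-state (or other) regression could not be performed."""


class SimulationError(IVPTError):
    """The synthetic-data generator was asked for something unstable/invalid."""
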