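"""Exception types shared across the package."""


class SpineFCError(Exception):
    """Base class for all package-specific errors."""


class SpikeTableFormatError(SpineFCError):
    """A spike table file is structurally malformed (missing columns, bad rows)."""


class TrialValidationError(SpineFCError):
    """A trial violates a data-model invariant (time range, unknown electrode, ...)."""


class ConfigurationError(SpineFCError):
    """A simulation or analysis configuration is infeasible or inconsistent."""
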