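"""Exception types shared across the package."""


class GlnRecycleError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(GlnRecycleError, ValueError):
    """A scenario, parameter set and model variant are mutually inconsistent."""


class IntegrationError(GlnRecycleError, RuntimeError):
    """The ODE solver failed (step-size collapse, non-finite state, or a
    state excursion below zero beyond solver tolerance)."""
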