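"""Exception hierarchy for polywear."""


class PolywearError(Exception):
    """Base class for all polywear errors."""


class ConfigurationError(PolywearError):
    """A bearing/protocol/schedule configuration violates a physical or
    numerical constraint (e.g. negative clearance, incompressible layer)."""


class InputError(PolywearError):
    """User-supplied input data (CSV waveforms, YAML config) is malformed."""


class SolverError(PolywearError):
    """The contact equilibrium solver failed to converge."""
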