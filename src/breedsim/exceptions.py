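"""Exception hierarchy shared across the package."""


class BreedSimError(Exception):
    """Base class for all breedsim errors."""


class FormatError(BreedSimError):
    """An input file does not conform to the expected CSV dialect."""


class ValidationError(BreedSimError, ValueError):
    """An argument or derived quantity violates a model constraint."""


class ConfigError(BreedSimError):
    """A scenario configuration is malformed or references unknown steps."""


class NotImplementedMethodError(BreedSimError, NotImplementedError):
    """A recognized evaluation method that this package deliberately omits."""
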