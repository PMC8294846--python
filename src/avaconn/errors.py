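"""Exception hierarchy for avaconn."""


class AvaconnError(Exception):
    """Base class for all avaconn errors."""


class ParameterError(AvaconnError, ValueError):
    """A parameter is outside its valid range."""


class DegenerateSignalError(AvaconnError, ValueError):
    """A signal cannot be processed (e.g. a constant region has no z-score)."""


class DegenerateGeneratorError(AvaconnError, ValueError):
    """A generator configuration cannot produce any activity."""


class UndefinedEstimateError(AvaconnError, ValueError):
    """The requested estimate is undefined for the given inputs."""


class PlacementError(AvaconnError, RuntimeError):
    """Perturbations cannot be placed under the separation constraints."""
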