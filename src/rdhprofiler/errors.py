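"""Exception types shared across the pipeline stages."""


class RdhProfilerError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RdhProfilerError, ValueError):
    """A parameter is outside its documented domain."""


class InputError(RdhProfilerError, ValueError):
    """Malformed or inconsistent input data."""


class CapacityError(RdhProfilerError, RuntimeError):
    """A request exceeds the available synthetic sequence space."""


class DistanceSaturationError(RdhProfilerError, ValueError):
    """Protein distance is undefined: identity below the saturation root."""


class NormalizationError(RdhProfilerError, ZeroDivisionError):
    """Single-copy marker mean is zero; coverage ratios are undefined."""


class ConfigurationError(RdhProfilerError, ValueError):
    """Invalid analysis configuration (e.g. no complete genomes)."""
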