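"""Exception hierarchy shared across the package."""


class VsnAdaptError(Exception):
    """Base class for all vsnadapt errors."""


class ProtocolError(VsnAdaptError, ValueError):
    """Invalid stimulation-protocol construction or validation failure."""


class GeneratorError(VsnAdaptError, ValueError):
    """Invalid synthetic-data configuration."""


class AnalysisError(VsnAdaptError, ValueError):
    """Analysis precondition violated (bad window, missing event, ...)."""
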