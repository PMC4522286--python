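"""Exception types shared across the package."""


class FFMError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FFMError, ValueError):
    """A builder or analysis operation received an out-of-domain parameter."""


class FormatError(FFMError, ValueError):
    """A trace or sidecar file violates the expected on-disk format."""


class AnalysisError(FFMError, ValueError):
    """An analysis precondition failed (e.g. recording shorter than protocol)."""
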