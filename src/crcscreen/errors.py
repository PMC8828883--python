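"""Exception hierarchy shared across the pipeline stages."""


class CrcScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CrcScreenError, ValueError):
    """A configuration object or file is invalid; the message names the field."""


class ParameterError(CrcScreenError, ValueError):
    """An operation received an out-of-domain parameter value."""


class InputError(CrcScreenError, ValueError):
    """Input data violates a precondition (mismatched ids, missing class, ...)."""


class BackendError(CrcScreenError, RuntimeError):
    """A segmentation backend failed on a slide; carries the slide id."""

    def __init__(self, slide_id: str, message: str) -> None:
        super().__init__(f"segmentation backend failed on slide {slide_id!r}: {message}")
        self.slide_id = slide_id
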