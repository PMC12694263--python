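"""Exception hierarchy shared across the package."""


class FuzzrulaError(Exception):
    """Base class for all package errors."""


class CodecError(FuzzrulaError):
    """Base class for frame/log codec errors."""


class MalformedFrameError(CodecError):
    """Frame has the wrong length."""


class UnknownFrameError(CodecError):
    """Frame header or type octet is not recognised."""


class RangeError(FuzzrulaError, ValueError):
    """A physical value lies outside the encodable range."""


class LogParseError(CodecError):
    """A text log row could not be parsed (strict mode)."""


class AlignmentError(FuzzrulaError, ValueError):
    """Series lengths disagree; align them to a common length first."""


class ModelValidationError(FuzzrulaError, ValueError):
    """A fuzzy model definition is inconsistent or incomplete."""


class InferenceError(FuzzrulaError):
    """No rule fired with positive strength and strict fallback is active."""


class ConfigError(FuzzrulaError, ValueError):
    """A pipeline or model configuration is invalid."""
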