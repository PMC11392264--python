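"""Exception hierarchy."""


class PolypsegError(Exception):
    """Base class for package errors."""


class InvalidSpecError(PolypsegError, ValueError):
    """A synthetic-data spec violates its invariants."""


class EmptyDatasetError(PolypsegError, ValueError):
    """No matched image/mask pairs were found."""


class CorruptInputError(PolypsegError, ValueError):
    """An image or mask file could not be decoded."""


class ConfigError(PolypsegError, ValueError):
    """An architecture/training configuration is inconsistent."""


class IncompatibleWeightsError(PolypsegError, ValueError):
    """A pretrained weight source does not match the configured widths."""


class DivergenceError(PolypsegError, RuntimeError):
    """Training produced a non-finite loss."""
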