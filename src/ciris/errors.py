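"""Exception and warning types used across the package."""


class CirisError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(CirisError):
    """A pipeline configuration file violates the schema.

    The message names the offending field with a dotted path
    (e.g. ``scenario.preset``) so problems can be fixed before any
    computation starts.
    """


class ContainerError(CirisError):
    """Base class for raw-data container format errors."""


class BadMagicError(ContainerError):
    """The file does not start with the expected magic bytes."""


class UnsupportedVersionError(ContainerError):
    """The container declares a format version this reader does not support."""


class TruncatedFileError(ContainerError):
    """The file ended in the middle of a header or record."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (file truncated at byte offset {offset})")
        self.offset = offset


class CirisWarning(UserWarning):
    """Non-fatal data irregularity (e.g. unpaired trailing cycles)."""
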