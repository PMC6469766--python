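"""Exception hierarchy shared across the package."""


class MitoproxError(Exception):
    """Base class for all package-specific errors."""


class ImageFormatError(MitoproxError):
    """The file on disk could not be parsed as a supported image format."""


class ConfigurationError(MitoproxError, ValueError):
    """Parameters, labels or manifest entries are inconsistent or invalid."""


class InputError(MitoproxError, ValueError):
    """Runtime inputs violate a contract (e.g. shape mismatch between masks)."""
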