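"""Exception hierarchy shared by all modules."""


class LtrForestError(Exception):
    """Base class for all package errors."""


class FormatError(LtrForestError):
    """A file does not conform to its declared format."""


class VocabularyError(LtrForestError):
    """An identifier does not resolve in the domain vocabulary."""


class ConsistencyError(LtrForestError):
    """Inputs that must agree with each other do not."""


class ConfigurationError(LtrForestError):
    """A run was requested with an invalid or incomplete configuration."""


class ModelVersionError(LtrForestError):
    """A model file was written by an incompatible format version."""
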