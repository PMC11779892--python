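"""Exception types shared across the package."""


class ClonotrackError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ClonotrackError):
    """A configuration value violates its documented constraints."""


class AirrFormatError(ClonotrackError):
    """An AIRR Rearrangement TSV is malformed (e.g. a mandatory column is absent)."""


class DataIntegrityError(ClonotrackError):
    """Inputs are individually valid but mutually inconsistent (e.g. a cell without a cluster label)."""
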