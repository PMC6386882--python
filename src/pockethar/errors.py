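"""Exception hierarchy shared across the package."""


class PocketHarError(Exception):
    """Base class for all pockethar errors."""


class FormatError(PocketHarError, ValueError):
    """A file or record violates the expected on-disk format."""


class DimensionError(PocketHarError, ValueError):
    """An array or vector has the wrong length or shape."""


class CompletenessError(PocketHarError, ValueError):
    """A recording is missing a required sensor trace."""


class ConfigError(PocketHarError, ValueError):
    """A configuration value violates its invariants."""
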