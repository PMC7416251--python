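"""Exception hierarchy shared across clusterlab modules."""


class ClusterlabError(Exception):
    """Base class for all clusterlab errors."""


class ParseError(ClusterlabError):
    """A delimited-text cell could not be parsed as a number."""


class InputError(ClusterlabError):
    """Input data violates a structural precondition (too few rows, bad shape)."""


class SpecError(ClusterlabError):
    """A generator/config specification is internally inconsistent."""


class ConfigError(ClusterlabError):
    """An option value is outside its allowed set."""


class DegeneracyError(ClusterlabError):
    """Data is too degenerate for the requested operation (e.g. < K distinct rows)."""


class UndefinedIndexError(ClusterlabError):
    """A validity index is undefined for the given partition (e.g. single cluster)."""


class NumericError(ClusterlabError):
    """Non-finite values where finite numbers are required."""
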