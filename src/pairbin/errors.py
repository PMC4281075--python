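"""Exception hierarchy shared across the package."""


class PairbinError(Exception):
    """Base class for all package errors."""


class ParseError(PairbinError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(PairbinError):
    """A loaded structure violates its invariants (missing parent, no root, ...)."""


class TaxonNotFoundError(PairbinError, KeyError):
    """A taxon id was looked up that is not present in the taxonomy."""


class UsageError(PairbinError, ValueError):
    """An operation was called with arguments outside its contract."""


class InputError(PairbinError):
    """User-supplied tabular input violates its contract (duplicates, unknown ids)."""


class ConfigurationError(PairbinError):
    """A simulation or binning configuration cannot be satisfied by the data."""
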