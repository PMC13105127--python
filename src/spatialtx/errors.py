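"""Exception hierarchy shared across the package."""


class SpatialTxError(Exception):
    """Base class for all package errors."""


class FormatError(SpatialTxError):
    """A file could be parsed but its structure contradicts its sidecars."""


class ValidationError(SpatialTxError):
    """Input violates a documented invariant."""


class EmptyResultError(SpatialTxError):
    """An operation produced an empty result that downstream stages cannot use."""
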