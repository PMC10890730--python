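"""Exception hierarchy shared across the package."""


class DarseqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DarseqError):
    """User-supplied configuration is inconsistent (e.g. unknown sample id)."""


class InputError(DarseqError):
    """An input file violates its format contract (unsorted VCF, bad GFF line...)."""
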