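"""Exception types shared across the package."""


class GeneAgeError(ValueError):
    """Base class for all validation and lookup errors raised by geneage."""


class ValidationError(GeneAgeError):
    """Malformed or inconsistent input (file contents, tables, parameters)."""


class LookupError_(GeneAgeError):
    """Unknown taxon, class or genome name."""
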