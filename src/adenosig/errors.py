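"""Exception types shared across the package."""


class AdenosigError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(AdenosigError, ValueError):
    """A user-supplied parameter or config field is invalid."""


class ReferenceMismatchError(AdenosigError, ValueError):
    """The REF allele of a variant does not match the reference genome."""


class ContextUnavailableError(AdenosigError, ValueError):
    """The trinucleotide context cannot be extracted (contig edge)."""


class RefitError(AdenosigError, ValueError):
    """Signature refitting is not possible for this input."""
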