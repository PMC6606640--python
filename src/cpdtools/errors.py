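"""Exception hierarchy shared by all cpdtools modules."""


class CpdError(Exception):
    """Base class for all cpdtools errors."""


class FormatError(CpdError):
    """A file does not conform to its expected external format."""


class ValidationError(CpdError):
    """A record violates a domain invariant (e.g. wt == mut)."""


class ConfigurationError(CpdError):
    """Inconsistent run configuration (e.g. a gene without an alignment)."""


class InsufficientDataError(CpdError):
    """Too few observations remain for the requested statistic."""


class UndefinedStatisticError(CpdError):
    """The requested quantity is undefined on this input (e.g. entropy of an
    all-gap column, severe fraction of an empty group)."""
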