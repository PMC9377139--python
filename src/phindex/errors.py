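"""Exception hierarchy shared across the pipeline."""


class PhindexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhindexError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(PhindexError, ValueError):
    """Malformed or unrecognised input records (unknown tool, bad table)."""


class IntervalError(PhindexError, ValueError):
    """Prophage intervals that overlap, are empty, or exceed contig bounds."""


class NormalizationError(PhindexError, ValueError):
    """A sample column cannot be normalized (e.g. all-zero counts)."""


class UndefinedStatisticError(PhindexError, ValueError):
    """A statistic is undefined on the given input (zero mean CV, constant
    vector correlation, empty coverage list)."""


class ConsistencyError(PhindexError, ValueError):
    """Structurally inconsistent inputs (contig in two bins, duplicate votes)."""
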