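"""Exception hierarchy shared by all pipeline stages."""


class CoexscreenError(Exception):
    """Base class for all package-specific errors."""


class DesignValidationError(CoexscreenError):
    """An experimental design violates one of its invariants."""


class TableParseError(CoexscreenError):
    """A measurement table file is malformed or inconsistent."""


class VocabularyError(CoexscreenError):
    """A strain/condition/gene label is not part of the design."""


class DomainError(CoexscreenError):
    """A numeric argument is outside its mathematical domain."""


class InsufficientDataError(CoexscreenError):
    """Too few data points for the requested statistic."""


class ConstantInputError(CoexscreenError):
    """A correlation was requested on a constant vector."""


class QuantificationError(CoexscreenError):
    """Ct-to-expression conversion failed (e.g. missing internal standard)."""
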