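"""Exception types shared across the package."""


class KinscreenError(Exception):
    """Base class for all package-specific errors."""


class DegenerateCurveError(KinscreenError):
    """A melt curve cannot be fitted (too few points, constant signal, ...)."""


class MissingReferenceError(KinscreenError):
    """Fewer than two QC-passing DMSO control wells for a kinase."""


class MalformedInputError(KinscreenError):
    """A domain object violates its documented invariants."""


class MalformedSequenceError(KinscreenError):
    """A protein sequence contains characters outside the 20 standard residues."""


class UndefinedRateError(KinscreenError):
    """A percentage was requested with a zero denominator."""


class LedgerInconsistencyError(KinscreenError):
    """Selection-ledger stage counts do not add up."""


class ParseError(KinscreenError):
    """An input file does not match the documented dialect."""
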