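"""Exception hierarchy shared across the package."""


class ReactivePdl1Error(Exception):
    """Base class for package errors."""


class FormatError(ReactivePdl1Error, ValueError):
    """A file violates the expected tabular layout (duplicates, bad cells)."""


class BarcodeParseError(FormatError):
    """A TCGA-style barcode cannot be parsed."""


class ValidationError(ReactivePdl1Error, ValueError):
    """Input values violate a documented precondition or invariant."""


class DegenerateInputError(ValidationError):
    """Statistically degenerate input (zero variance, all ties, ...)."""


class AlignmentError(ValidationError):
    """Two inputs that must share sample/cohort sets do not."""


class GeneNotFoundError(ReactivePdl1Error, KeyError):
    """A requested gene is absent from the expression matrix."""


class EstimationError(ReactivePdl1Error, RuntimeError):
    """A model fit cannot be carried out (e.g. no observed events)."""


class ConvergenceError(EstimationError):
    """An iterative fit failed to converge (e.g. monotone partial likelihood)."""
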