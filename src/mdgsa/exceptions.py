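"""Exception hierarchy for mdgsa."""


class MdgsaError(Exception):
    """Base class for all mdgsa errors."""


class ParseError(MdgsaError):
    """A gene-set or ranking file is malformed."""


class EmptyInputError(MdgsaError):
    """An operation received (or produced) no usable rows."""


class DegenerateSetError(MdgsaError):
    """A membership indicator has only one class; the model cannot be fitted."""


class DegenerateCovariateError(MdgsaError):
    """A covariate column has zero variance."""


class CollinearityError(MdgsaError):
    """The design matrix is numerically rank-deficient."""


class InvalidPValueError(MdgsaError):
    """A p-value outside [0, 1] was supplied."""


class InvalidStandardErrorError(MdgsaError):
    """A non-positive standard error was supplied to a Wald test."""


class WrongModelError(MdgsaError):
    """A bivariate-only operation was applied to a univariate fit."""


class InsufficientDataError(MdgsaError):
    """Too few points for the requested summary."""


class CapacityError(MdgsaError):
    """Requested disjoint gene sets do not fit in the universe."""
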