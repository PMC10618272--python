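"""Exception and warning types shared across the package."""


class MolprefError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MolprefError, ValueError):
    """A SMILES string could not be parsed into a molecule."""


class EmptyAfterStripError(ParseError):
    """Standardization left no organic fragment to keep."""


class BadPatternError(MolprefError, ValueError):
    """A structural-alert SMARTS pattern failed to compile."""


class NotFittedError(MolprefError, RuntimeError):
    """A transform was requested before the corresponding fit."""


class DimensionError(MolprefError, ValueError):
    """Feature dimensionality does not match the model input layer."""


class LabelError(MolprefError, ValueError):
    """A preference label outside {0, 1} was supplied."""


class InfeasibleBatchError(MolprefError, RuntimeError):
    """Pair-generation constraints cannot yield the requested batch."""


class ShapeError(MolprefError, ValueError):
    """A ratings table is ragged or otherwise malformed."""


class LengthError(MolprefError, ValueError):
    """Two rating sequences differ in length."""


class DegenerateSetError(MolprefError, ValueError):
    """A score set is too small or constant for the requested statistic."""


class ConvergenceWarning(UserWarning):
    """Training ended with a higher loss than it started with."""
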