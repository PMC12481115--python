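"""Exception hierarchy for the emgsynergy pipeline.

Most errors subclass ValueError so callers that only care about "bad input"
can catch broadly, while tests can assert the precise failure mode.
"""


class EmgSynergyError(ValueError):
    """Base class for all pipeline errors."""


# --- I/O and preprocessing -------------------------------------------------

class ParseError(EmgSynergyError):
    """A delimited-text cell could not be parsed as a number."""


class FormatError(EmgSynergyError):
    """Structurally malformed input (ragged rows, bad manifest, ...)."""


class SignalTooShortError(EmgSynergyError):
    """Trial shorter than the filter's minimum padding requirement."""


class BoundsError(EmgSynergyError):
    """Requested window lies outside the recorded samples."""


class ConstantChannelError(EmgSynergyError):
    """A muscle channel is constant (cannot be scaled to unit variance)."""


class InsufficientTrialsError(EmgSynergyError):
    """Fewer trials available than requested for assembly."""


# --- decomposition ---------------------------------------------------------

class OrderError(EmgSynergyError):
    """Requested model order outside 1..n_muscles (or cluster count < 1)."""


class DataError(EmgSynergyError):
    """Non-finite or negative values where nonnegative data is required."""


class UndefinedVAFError(EmgSynergyError):
    """VAF undefined: data or reconstruction is identically zero."""


class ShapeError(EmgSynergyError):
    """Array shape incompatible with the operation."""


# --- clustering / matching -------------------------------------------------

class LabelError(EmgSynergyError):
    """Inconsistent muscle labels across pooled decompositions."""


class EmptySetError(EmgSynergyError):
    """An operation received an empty collection."""


class InsufficientSampleError(EmgSynergyError):
    """Too few subjects/observations for the statistical comparison."""


# --- sparseness / fractionation -------------------------------------------

class UndefinedSparsenessError(EmgSynergyError):
    """Sparseness undefined for the all-zero vector."""


class DimensionError(EmgSynergyError):
    """Vector too short for the sparseness index (needs n >= 2)."""


class InsufficientBasisError(EmgSynergyError):
    """Fewer than two basis vectors for fractionation/merging."""


class UndefinedEffectError(EmgSynergyError):
    """Cohen's d undefined: pooled standard deviation is zero."""


# --- synthetic data --------------------------------------------------------

class FeasibilityError(EmgSynergyError):
    """Template constraints unsatisfiable within the attempt budget."""


class SplitError(EmgSynergyError):
    """Parent synergy support too small to fractionate."""


class ParameterError(EmgSynergyError):
    """Invalid generator parameter (e.g. negative noise scale)."""
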