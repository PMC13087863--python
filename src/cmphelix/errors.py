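"""Exception hierarchy.

Every error raised by the library derives from :class:`CmphelixError` so that
callers (and the CLI, which maps error classes to exit codes) can catch the
whole family at once.
"""


class CmphelixError(Exception):
    """Base class for all cmphelix errors."""


# -- palette / sequences ----------------------------------------------------
class UnknownResidue(CmphelixError):
    """A one-letter code is not present in the palette."""


class InvalidPosition(CmphelixError):
    """A residue is not allowed at its slot in the hexamer repeat."""


class EmptyPalette(CmphelixError):
    """The palette defines no x- or no y-eligible residues."""


# -- fingerprints / embedding -----------------------------------------------
class DisconnectedGraph(CmphelixError):
    """The molecular graph has more than one connected component."""


class TooFewSamples(CmphelixError):
    """Not enough fingerprints to fit the requested embedding."""


class DimensionMismatch(CmphelixError):
    """Vector length incompatible with a fitted model."""


# -- melt calling -----------------------------------------------------------
class NegativeTime(CmphelixError):
    pass


class EmptyTrajectory(CmphelixError):
    pass


class IrregularSpacing(CmphelixError):
    """Trajectory frame times are not uniformly spaced."""


class AllCensored(CmphelixError):
    """No replicate produced a melt event."""


# -- GPR surrogate ----------------------------------------------------------
class NonFiniteInput(CmphelixError):
    pass


class SingularKernel(CmphelixError):
    """Kernel matrix not positive definite even after jitter escalation."""


# -- acquisition / campaign -------------------------------------------------
class EmptyBatch(CmphelixError):
    pass


class PoolTooSmall(CmphelixError):
    pass


class LibraryTooSmall(CmphelixError):
    pass


class OracleFailure(CmphelixError):
    """The Tm oracle raised while evaluating a candidate."""


# -- TICA / WHAM ------------------------------------------------------------
class LagTooLarge(CmphelixError):
    pass


class RankDeficientCovariance(CmphelixError):
    pass


class NoOverlap(CmphelixError):
    """An umbrella window shares no occupied bin with any other window."""


class NotConverged(CmphelixError):
    pass


class SingleBasin(CmphelixError):
    """The PMF exposes fewer than two local minima after smoothing."""


class StepSizeUnstable(CmphelixError):
    """Langevin integration produced divergent samples."""


class InconsistentParams(CmphelixError):
    pass


# -- composition analysis ---------------------------------------------------
class LengthMismatch(CmphelixError):
    pass


class ConstantInput(CmphelixError):
    """Rank correlation undefined for a constant series."""


class DegenerateDesign(CmphelixError):
    """All composition rows identical; regression undefined."""


# -- IO ---------------------------------------------------------------------
class SchemaError(CmphelixError):
    """Columns of an input table could not be identified."""


class ValidationError(CmphelixError):
    """A table row failed sequence validation."""
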