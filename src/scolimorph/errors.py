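"""Exception hierarchy for scolimorph.

All package-specific errors derive from :class:`ScolimorphError` so callers can
catch the whole family with one clause.
"""


class ScolimorphError(Exception):
    """Base class for all scolimorph errors."""


# --- landmark I/O and validation -------------------------------------------

class ParseError(ScolimorphError):
    """A landmark file row could not be parsed."""


class VocabularyError(ParseError):
    """A landmark code or bone label outside the closed vocabulary."""


class DuplicateError(ParseError):
    """The same (bone, code) pair appeared more than once."""


class MissingApexError(ScolimorphError):
    """Sacral apex required for frame alignment but not supplied."""


class MissingLandmarkError(ScolimorphError):
    """A required landmark is absent from the set."""


class IncompleteLandmarksError(ScolimorphError):
    """A vertebra does not carry the full landmark complement."""


# --- geometry ---------------------------------------------------------------

class CoplanarPointsError(ScolimorphError):
    """Sphere fitting attempted on (near-)coplanar points."""


class ConvergenceError(ScolimorphError):
    """Iterative refinement failed to converge."""


class DegenerateSelectionError(ScolimorphError):
    """Anterior-surface selection returned too few vertices."""


class DegenerateFrameError(ScolimorphError):
    """Landmark configuration does not define a proper body frame."""


class ZeroDistanceError(ScolimorphError):
    """A scaling distance evaluated to zero."""


# --- model building ---------------------------------------------------------

class TemplateError(ScolimorphError):
    """Template bundle is missing a body, mesh or landmark set."""


class LevelMismatchError(ScolimorphError):
    """Two per-level collections do not cover the same levels."""


class MissingL5Error(ScolimorphError):
    """L5 centre required as the reference but absent."""


class MissingFrameError(ScolimorphError):
    """A body frame needed for an angle computation is undefined."""


class InsufficientLevelsError(ScolimorphError):
    """Too few vertebral centres for the requested polynomial fit."""


# --- statistics -------------------------------------------------------------

class SingletonGroupError(ScolimorphError):
    """Displacements need at least two observations per group."""


class DegenerateVarianceError(ScolimorphError):
    """Reliability coefficient undefined because total variance is zero."""


class SmallSampleError(ScolimorphError):
    """Sample too small for the requested test."""


class InsufficientBlocksError(ScolimorphError):
    """Friedman-type test needs blocks observed in at least two groups."""


class UnknownControlError(ScolimorphError):
    """Post-hoc control group not present in the data."""


# --- synthetic --------------------------------------------------------------

class SpecError(ScolimorphError):
    """Invalid or unreachable synthetic spine specification."""
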