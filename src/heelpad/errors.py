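"""Exception hierarchy for the heel-pad analysis pipeline.

Every error raised by the package derives from :class:`HeelpadError`, so
callers can fence off the whole pipeline with one ``except``. Errors raised
inside :func:`heelpad.mechanics.analyze_trial` are re-tagged with the failing
stage via :class:`StageError`.
"""

from __future__ import annotations


class HeelpadError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(HeelpadError, ValueError):
    """A configuration value or key is invalid; the message names the key."""


class DegenerateGeometryError(HeelpadError, ValueError):
    """Ball centers are collinear or duplicated; no plane is defined."""


class EmptyInputError(HeelpadError, ValueError):
    """An operation received an empty series, cloud, or record list."""


class NoContactError(HeelpadError, ValueError):
    """No frame satisfies the contact-force criterion."""


class DegenerateTrajectoryError(HeelpadError, ValueError):
    """Stance too short to form a trajectory (fewer than 3 frames)."""


class InvalidStateError(HeelpadError, ValueError):
    """A derived channel was requested before its prerequisites were set."""


class UnitError(HeelpadError, ValueError):
    """A physically impossible unit combination (e.g. zero area in contact)."""


class UnidentifiableModelError(HeelpadError, ValueError):
    """The regressor matrix of the viscoelastic fit is rank deficient."""


class DegenerateCurveError(HeelpadError, ValueError):
    """The loading branch encloses no positive area; EDR is undefined."""


class InsufficientDataError(HeelpadError, ValueError):
    """Too few observations for the requested statistic."""


class AllTiesError(HeelpadError, ValueError):
    """Every paired difference is zero; the signed-rank test is undefined."""


class SchemaError(HeelpadError, ValueError):
    """A file does not match the documented CSV/JSON schema."""


class DegenerateLoopWarning(UserWarning):
    """Strain is monotone: the unloading branch collapses to a single frame."""


class StageError(HeelpadError):
    """Wraps an error raised inside a named stage of trial analysis."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
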