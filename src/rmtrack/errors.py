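"""Exception hierarchy for rmtrack.

All package errors derive from :class:`RMTrackError` so callers can catch
pipeline failures without masking programming errors.
"""


class RMTrackError(Exception):
    """Base class for all rmtrack errors."""


class TrackFormatError(RMTrackError):
    """A track table is missing a required column or is otherwise unmappable."""


class TrackIntegrityError(RMTrackError):
    """A track table violates a structural rule (e.g. duplicate (cell, frame))."""


class TrackParseError(RMTrackError):
    """A cell of the track table could not be parsed as a number."""


class InsufficientDataError(RMTrackError):
    """A kinematic operation was asked of a track/segment with < 2 points."""


class DegenerateDataError(RMTrackError):
    """Point set too small or too concentrated for a density estimate."""


class ParameterError(RMTrackError):
    """An invalid parameter value; the message names the offending field."""


class AlignmentError(RMTrackError):
    """An operation requiring spheroid-aligned coordinates got a raw track."""


class PipelineError(RMTrackError):
    """A pipeline stage failed; the message names the stage and cells."""
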