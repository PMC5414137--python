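"""Exception hierarchy for the automated Modified Jebsen Test pipeline."""


class MjtError(Exception):
    """Base class for all package-specific errors."""


class CorruptRecordingError(MjtError):
    """An RGB/depth frame pair is missing or mismatched on disk."""

    def __init__(self, index, message=None):
        self.index = index
        super().__init__(message or f"corrupt recording: bad frame pair at index {index}")


class EmptyRecordingError(MjtError):
    """A recording source contains no frames."""


class TimesTableError(MjtError):
    """A timing-table CSV violates the schema or its internal consistency."""


class SceneError(MjtError):
    """A static scene structure could not be detected."""


class EdgeNotFoundError(SceneError):
    """No table-edge transition exists in the bottom half of the depth image."""


class RidgeNotFoundError(SceneError):
    """No connected group passed the ridge length filter."""


class AmbiguousRidgeError(SceneError):
    """More than one connected group passed the ridge length filter."""


class CanNotFoundError(SceneError):
    """The Circle Hough Transform produced no acceptable circle."""


class StartNotDetectedError(MjtError):
    """The hand never satisfied the subtest's distance-crossing condition."""


class HandGapError(MjtError):
    """The hand was absent for more consecutive frames than tolerated."""


class SubtestIncompleteError(MjtError):
    """The recording ended before the subtest's finish condition occurred."""

    def __init__(self, subtest, detail, count=None):
        self.subtest = subtest
        self.count = count
        super().__init__(f"subtest incomplete ({subtest}): {detail}")
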