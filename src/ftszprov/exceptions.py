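"""Exception hierarchy. Every error the pipeline raises derives from FtszProvError."""


class FtszProvError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(FtszProvError, ValueError):
    pass


class AlphabetError(FtszProvError, ValueError):
    """A sequence contains a character outside the amino-acid alphabet."""


class ConfigurationError(FtszProvError, ValueError):
    pass


class MissingIdError(FtszProvError, KeyError):
    pass


class ModelDegenerateError(FtszProvError, ValueError):
    """A profile HMM could not be built (e.g. zero match columns)."""


class CalibrationError(FtszProvError, RuntimeError):
    pass


class StateError(FtszProvError, RuntimeError):
    """Operation requires a state (e.g. calibration) the object lacks."""


class EmptyAlignmentError(FtszProvError, ValueError):
    """Trimming removed every column."""


class IncomparablePairError(FtszProvError, ValueError):
    """A sequence pair shares no mutually ungapped alignment column."""

    def __init__(self, pair):
        self.pair = pair
        super().__init__(f"no comparable columns for pair {pair[0]!r}, {pair[1]!r}")


class DegenerateTreeError(FtszProvError, ValueError):
    pass


class ScheduleError(FtszProvError, ValueError):
    """An event schedule is inconsistent with its species tree."""

    def __init__(self, event_id, message):
        self.event_id = event_id
        super().__init__(f"event {event_id}: {message}")


class DataIntegrityError(FtszProvError, ValueError):
    pass


class MissingTaxonomyError(FtszProvError, KeyError):
    pass


class AnchorNotFoundError(FtszProvError, ValueError):
    """No N-terminal domain hit on a sequence, so no C-terminus anchor."""


class GroupTooSmallError(FtszProvError, ValueError):
    pass


class PipelineError(FtszProvError, RuntimeError):
    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")
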