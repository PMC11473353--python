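"""Exception hierarchy for socimotor.

Every error raised on purpose by this package derives from
:class:`SocimotorError`, so callers can catch one type at the CLI
boundary while tests can assert on the specific subclass.
"""


class SocimotorError(Exception):
    """Base class for all socimotor errors."""


class FormatError(SocimotorError):
    """A file does not conform to the expected tabular layout."""


class SamplingError(SocimotorError):
    """Timestamps are not uniform at the declared sampling rate."""

    def __init__(self, msg, gap_index=None):
        super().__init__(msg)
        self.gap_index = gap_index


class ManifestError(SocimotorError):
    """A session manifest is structurally invalid."""


class AlignmentError(SocimotorError):
    """Sensor streams of one session share no overlapping interval."""


class DataError(SocimotorError):
    """Non-finite or otherwise unusable sample values."""


class InputError(SocimotorError):
    """An operation received arguments outside its contract."""


class DegenerateDataError(SocimotorError):
    """Data carry no variability where variability is required."""


class SampleSizeError(SocimotorError):
    """Too few observations for a statistically meaningful estimate."""


class DomainError(SocimotorError):
    """Values outside the mathematical domain of an estimator."""


class RateError(SocimotorError):
    """A simulator spike rate incompatible with the bump kernel grid."""


class TrainingError(SocimotorError):
    """A classifier stratum cannot be trained (e.g. single class)."""
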