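"""Exception hierarchy for saccvigor."""


class SaccvigorError(Exception):
    """Base class for all saccvigor errors."""


class InvalidGeometryError(SaccvigorError, ValueError):
    """Task geometry violates its invariants (e.g. more targets than candidates)."""


class CounterbalanceError(SaccvigorError, ValueError):
    """Trial counts cannot be divided evenly across condition cells."""


class DegenerateWaveformError(SaccvigorError, ValueError):
    """Requested saccade too small to be represented at the sampling step."""


class CohortError(SaccvigorError, ValueError):
    """Cohort too small for downstream statistics."""


class FormatError(SaccvigorError, ValueError):
    """A gaze/metadata file does not conform to the declared dialect."""


class DegenerateInputError(SaccvigorError, ValueError):
    """Input too short or empty for the requested computation."""


class FitError(SaccvigorError, RuntimeError):
    """Main-sequence fit failed to converge or is unidentifiable."""


class IncompleteDesignError(SaccvigorError, ValueError):
    """Repeated-measures design has missing cells."""
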