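"""Exception hierarchy for swgsd."""


class SWGSDError(Exception):
    """Base class for all swgsd errors."""


class InvalidDesignError(SWGSDError):
    """A structural design parameter (C, T, analysis schedule, ...) is invalid."""


class InvalidScheduleError(InvalidDesignError):
    """An explicit switch schedule is inconsistent with the cluster count."""


class InestimableEffectError(SWGSDError):
    """The treatment effect is not estimable from the data available at an analysis."""


class InfeasibleDesignError(SWGSDError):
    """No design satisfying the requested operating characteristics exists.

    Raised e.g. when interim boundaries cross (f_t > e_t) or the power
    constraint cannot be met within the sample-size cap.
    """


class ConfigurationError(SWGSDError):
    """Mismatched or invalid run configuration (schema violations, inconsistent objects)."""


class NumericalError(SWGSDError):
    """A root could not be bracketed or an optimiser failed to converge."""
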