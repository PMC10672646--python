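"""Exception hierarchy for organofit."""


class OrganofitError(Exception):
    """Base class for all organofit errors."""


class InvalidStateError(OrganofitError, ValueError):
    """A compartment state is negative, NaN or infinite."""


class SimulationError(OrganofitError, RuntimeError):
    """The IVP solver failed or produced an inadmissible trajectory."""


class UndefinedFractionError(OrganofitError, ValueError):
    """Composition fractions requested at an all-zero state."""


class InsufficientDataError(OrganofitError, ValueError):
    """Too few measurement rows to pose the least-squares problem."""


class RankDeficiencyError(OrganofitError, ValueError):
    """The normal equations are singular beyond tolerance."""


class DataValidationError(OrganofitError, ValueError):
    """Input measurement table failed validation."""


class SpecificationError(OrganofitError, ValueError):
    """A cohort specification is internally inconsistent."""
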