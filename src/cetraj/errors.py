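"""Exception hierarchy for the cetraj pipeline.

Every stage raises a subclass of :class:`CetrajError`, so callers (and the
command-line driver) can distinguish user-facing input problems from
numerical failures.
"""


class CetrajError(Exception):
    """Base class for all cetraj errors."""


class CohortFormatError(CetrajError):
    """A cohort file violates the column contract (missing/renamed columns)."""


class CohortIntegrityError(CetrajError):
    """Internally inconsistent cohort data (duplicate person-waves, unknown ids)."""


class DegenerateInputError(CetrajError):
    """Input with no usable variation (e.g. zero pooled SD when standardising)."""


class OutOfSupportError(CetrajError):
    """A matching variable falls outside the coarsening bins."""


class ConfigError(CetrajError):
    """Invalid simulation or run configuration."""


class ConvergenceError(CetrajError):
    """Mixed-model estimation failed to converge."""


class SpecificationError(CetrajError):
    """A model term required by the requested operation is absent."""
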