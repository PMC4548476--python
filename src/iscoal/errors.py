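"""Exception hierarchy.

``IscoalError`` is the common base so callers can catch everything the
library raises deliberately; subclasses distinguish bad input data from
resource exhaustion and sampler pathologies.
"""


class IscoalError(Exception):
    """Base class for all errors raised by iscoal."""


class DataFormatError(IscoalError):
    """A dataset file could not be parsed in its declared dialect."""


class DataValidationError(IscoalError):
    """A dataset or configuration violates a model invariant."""


class StuckConfigurationError(DataValidationError):
    """A non-MRCA ancestral configuration admits no backward event.

    This signals data that is not reachable from an all-zero root,
    i.e. not a perfect phylogeny under the infinite-sites model.
    """


class AbsoluteContinuityError(IscoalError):
    """A proposal assigned zero weight to every event of a reachable
    configuration, so q(G) = 0 somewhere p(G) > 0."""


class ExactBudgetExceededError(IscoalError):
    """The exact-recursion memo grew past its configured key ceiling."""
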