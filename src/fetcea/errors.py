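"""Exception hierarchy for the cost-effectiveness analysis."""


class CeaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CeaError):
    """A model specification file or in-memory spec is invalid.

    Messages name the offending field path (e.g. ``nodes.N3.value``).
    """


class ValidationError(CeaError, ValueError):
    """A domain object received an invalid value (e.g. negative fee amount)."""


class UndefinedEffectivenessError(CeaError):
    """The effectiveness denominator (confirmed-TRC mass) is zero.

    Raised instead of silently dividing: with no confirmed
    treatment-related-change lesions the identification rate has no meaning.
    """


class UndefinedRatioError(CeaError):
    """ICER/CER denominator (effectiveness or incremental effectiveness) is ~0."""


class NodeEstimationError(CeaError):
    """A chance-node proportion is requested over an empty conditioning subset."""


class InconsistentCohortError(CeaError):
    """The requested node probabilities admit no valid joint lesion distribution."""


class RejectionBudgetError(CeaError):
    """Positive-truncation rejection sampling exhausted its redraw budget."""


class PsaError(CeaError):
    """Monte Carlo analysis failed (e.g. too many degenerate draws)."""


class StageError(CeaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
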