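"""Exception hierarchy for kdscore."""


class KdScoreError(Exception):
    """Base class for all kdscore errors."""


class UnitError(KdScoreError):
    """Unsupported analyte/unit combination."""


class SchemaError(KdScoreError):
    """Cohort file does not match the declared schema."""


class ParseError(KdScoreError):
    """A row of a cohort file could not be parsed.

    Carries the offending row identifiers in ``row_ids``.
    """

    def __init__(self, message: str, row_ids=()):
        super().__init__(message)
        self.row_ids = list(row_ids)


class ValidationError(KdScoreError):
    """Cohort-level invariant violated (e.g. duplicate patient ids)."""


class ConfigurationError(KdScoreError):
    """A score model definition is inconsistent or references unknown variables."""


class InputError(KdScoreError):
    """Invalid argument to a statistical routine."""


class UndefinedAUCError(InputError):
    """ROC AUC requested for a single-class label vector."""


class PipelineError(KdScoreError):
    """End-to-end run cannot proceed (e.g. no labeled patients)."""
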