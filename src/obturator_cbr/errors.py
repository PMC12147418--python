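"""Exception hierarchy shared across the package."""


class ObturatorCBRError(Exception):
    """Base class for all package errors."""


class SchemaError(ObturatorCBRError):
    """A case table is structurally unusable (e.g. a required column is absent)."""


class IntegrityError(ObturatorCBRError):
    """A case base violates an integrity constraint (e.g. duplicate case IDs)."""


class VocabularyError(ObturatorCBRError):
    """A value is not a member of its attribute's controlled vocabulary."""


class CaseValidationError(ObturatorCBRError):
    """One or more case records do not conform to their class schema."""

    def __init__(self, message: str, issues=None):
        super().__init__(message)
        self.issues = list(issues) if issues is not None else []


class InterviewOrderError(ObturatorCBRError):
    """An answer was supplied for a question that is not currently pending."""


class IncompleteInterviewError(ObturatorCBRError):
    """A query was requested from an interview that still has pending questions."""

    def __init__(self, message: str, missing_keys=None):
        super().__init__(message)
        self.missing_keys = list(missing_keys) if missing_keys is not None else []


class ClassMismatchError(ObturatorCBRError):
    """Confidence was requested between records of different Aramany classes."""


class UndefinedScoreError(ObturatorCBRError):
    """No attribute is comparable between query and case, so no score exists."""


class ConstantInputError(ObturatorCBRError):
    """Rank correlation is undefined for a constant input vector."""


class EmptyInputError(ObturatorCBRError):
    """An operation that needs at least one observation received none."""


class BoundsError(ObturatorCBRError):
    """A rank cutoff k exceeds the number of retrieved items."""


class ConfigError(ObturatorCBRError):
    """A generator or weight configuration is invalid."""


class GenerationError(ObturatorCBRError):
    """The synthetic generator could not satisfy the requested constraints."""
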