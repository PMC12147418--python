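"""The dynamic clinical interview that describes a new maxillectomy case.

The interview starts by asking for the Aramany class of the defect; every
subsequent question comes from that class's schema, in schema order, with
skip logic evaluated against the answers already given (for example, a case
with no bounded edentulous spaces is never asked where those spaces are).
A completed interview yields a :class:`QuerySpec` — the same attribute map a
stored :class:`~obturator_cbr.case_model.CaseRecord` carries, minus media —
which the matcher scores against the case base.

States are immutable: :func:`apply_answer` returns a new state, so an
interview is a pure fold over its answer sequence and identical transcripts
always produce identical queries.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

from . import case_model as cm
from .errors import (
    IncompleteInterviewError,
    InterviewOrderError,
    VocabularyError,
)

__all__ = [
    "Question",
    "InterviewState",
    "QuerySpec",
    "next_question",
    "apply_answer",
    "build_query",
    "replay_transcript",
]

_PROMPTS: dict[str, str] = {
    cm.ARAMANY_CLASS_KEY: "Aramany class of the maxillectomy defect",
    cm.NEAREST_ABUTMENT: "Nearest abutment tooth to the defect (FDI code)",
    cm.LAST_TOOTH: "Last remaining tooth that may be involved in the restoration (FDI code)",
    cm.DEFECT_EXTENSION: "Extension of the defect",
    cm.ABUTMENT_CONDITION: "Condition of the nearest abutment",
    cm.BOUNDED_SPACE_COUNT: "Number of bounded edentulous spaces in the remaining dentition",
    cm.BOUNDED_SPACE_LOCATION: "Location of the bounded edentulous spaces",
    cm.BOUNDED_SPACE_DISTRIBUTION: "Distribution of the bounded edentulous spaces",
    cm.ORONASAL_CONNECTION: "Size of the oronasal connection",
    cm.DEFECT_SIDE_REMAINING_TEETH: "Remaining teeth on the defect side",
    cm.ARCH_CLASSIFICATION: "Classification of the dental arch",
    cm.POSTERIOR_ABUTMENTS: "Most posterior abutment tooth (FDI code)",
    cm.BOTH_PREMOLARS_PRESENT: "Are both premolars present?",
    cm.REMAINING_MOLAR_COUNT: "Number of remaining molars",
}


def prompt_for(key: str) -> str:
    """Display text for a question key; side-suffixed keys get a side tag."""
    for suffix, side in ((cm.RIGHT, "right"), (cm.LEFT, "left")):
        if key.endswith(suffix):
            return f"{_PROMPTS[key[: -len(suffix)]]} — {side} side"
    return _PROMPTS[key]


@dataclass(frozen=True)
class Question:
    key: str
    prompt: str
    choices: tuple[str, ...]


@dataclass(frozen=True)
class InterviewState:
    """An in-progress interview: the declared class plus the answers so far."""

    aramany_class: cm.AramanyClass | None = None
    answers: tuple[tuple[str, str], ...] = ()

    @property
    def answers_dict(self) -> dict[str, str]:
        return dict(self.answers)

    @property
    def complete(self) -> bool:
        return next_question(self) is None


@dataclass(frozen=True)
class QuerySpec:
    """The attribute description of a new case produced by the interview."""

    aramany_class: cm.AramanyClass
    attributes: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", dict(self.attributes))

    def validate(self) -> list[cm.ValidationIssue]:
        return cm.validate_attributes(self.aramany_class, self.attributes)


def next_question(state: InterviewState) -> Question | None:
    """The first unanswered applicable question, or None when complete.

    The class question always comes first; afterwards the class schema is
    walked front to back and the first applicable key not yet answered is
    returned.  Deterministic in the state.
    """
    if state.aramany_class is None:
        return Question(
            cm.ARAMANY_CLASS_KEY,
            _PROMPTS[cm.ARAMANY_CLASS_KEY],
            tuple(c.value for c in cm.AramanyClass),
        )
    answered = state.answers_dict
    schema = cm.schema_for_class(state.aramany_class)
    for item in schema.items:
        if item.key not in answered and item.applicable(answered):
            return Question(
                item.key,
                prompt_for(item.key),
                cm.vocabulary_for(state.aramany_class, item.key),
            )
    return None


def apply_answer(state: InterviewState, key: str, value: str) -> InterviewState:
    """Record the answer to the currently pending question.

    Only the pending question's key is accepted — feeding answers out of
    order (or for a question the skip logic suppressed) is an
    :class:`InterviewOrderError`; a value outside the question's choices is a
    :class:`VocabularyError`.  The input state is never mutated.
    """
    pending = next_question(state)
    if pending is None:
        raise InterviewOrderError(
            f"interview already complete; unexpected answer for {key!r}")
    if key != pending.key:
        raise InterviewOrderError(
            f"expected an answer for {pending.key!r}, got {key!r}")
    if value not in pending.choices:
        raise VocabularyError(
            f"{value!r} is not a valid answer for {key!r}; "
            f"choices: {list(pending.choices)}")
    if key == cm.ARAMANY_CLASS_KEY:
        return replace(state, aramany_class=cm.AramanyClass(value))
    return replace(state, answers=state.answers + ((key, value),))


def build_query(state: InterviewState) -> QuerySpec:
    """Turn a completed interview into a QuerySpec.

    Raises :class:`IncompleteInterviewError` (listing the currently
    applicable unanswered keys) if any question is still pending.
    """
    if state.aramany_class is None:
        raise IncompleteInterviewError(
            "the Aramany class has not been declared",
            missing_keys=[cm.ARAMANY_CLASS_KEY])
    answered = state.answers_dict
    schema = cm.schema_for_class(state.aramany_class)
    missing = [k for k in schema.applicable_keys(answered) if k not in answered]
    if missing:
        raise IncompleteInterviewError(
            f"interview incomplete; pending: {missing}", missing_keys=missing)
    return QuerySpec(state.aramany_class, answered)


def replay_transcript(
    answers: Iterable[tuple[str, str]] | Mapping[str, str],
) -> QuerySpec:
    """Replay an ordered (key, value) transcript non-interactively.

    Equivalent to applying each answer through :func:`apply_answer`, so the
    transcript must follow schema order, start with ``aramany_class`` and
    contain no answer for a skipped question.
    """
    pairs: Sequence[tuple[str, str]]
    if isinstance(answers, Mapping):
        pairs = list(answers.items())
    else:
        pairs = list(answers)
    state = InterviewState()
    for key, value in pairs:
        state = apply_answer(state, key, value)
    return build_query(state)
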