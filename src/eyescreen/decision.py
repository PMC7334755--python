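"""The referral decision engine and its seven development iterations.

The final (seventh) rule set refers a participant when any of the following
triggers fires:

* under-6s: the guardian reports any eye problem today;
* age 6+: presenting distance acuity worse than 6/12 in either eye;
* age 6+: self-reported eye pain or discomfort today;
* age 6+: self-reported difficulty seeing far or near objects;
* age 40+: inability to read N8 print at 33 cm.

Earlier iterations used subsets and variants of these rules — a catch-all
"any eye problem" question (unlimited duration, then restricted to "today"),
optional vs mandatory distance acuity, pain-only vs pain-or-discomfort —
and :func:`catalog` enumerates all seven in order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .acuity import VisualAcuity, parse_snellen, worse_than
from .records import (
    NEAR_VISION_AGE,
    NearVisionResult,
    ParticipantRecord,
    TriState,
)

__all__ = [
    "SymptomQuestion",
    "ProblemScope",
    "ReferralReason",
    "AlgorithmVersion",
    "ReferralDecision",
    "DecisionError",
    "decide",
    "catalog",
    "DEFAULT_VA_THRESHOLD",
]

#: Referral threshold for distance acuity: refer when worse than this.
DEFAULT_VA_THRESHOLD: VisualAcuity = parse_snellen("6/12")


class DecisionError(ValueError):
    """A field required by the algorithm version is missing from the record."""


class SymptomQuestion(str, enum.Enum):
    ANY_EYE_PROBLEM = "any_eye_problem"
    EYE_PAIN = "eye_pain"
    EYE_PAIN_OR_DISCOMFORT = "eye_pain_or_discomfort"
    VISION_DIFFICULTY = "vision_difficulty"


class ProblemScope(str, enum.Enum):
    """Duration scope of the catch-all "any eye problem" question."""

    ANY_DURATION = "any_duration"
    TODAY_ONLY = "today_only"


class ReferralReason(str, enum.Enum):
    CHILD_PROBLEM = "child_problem"
    ANY_EYE_PROBLEM = "any_eye_problem"
    PAIN_OR_DISCOMFORT = "pain_or_discomfort"
    VISION_DIFFICULTY = "vision_difficulty"
    LOW_DISTANCE_VA = "low_distance_va"
    NEAR_VISION_FAIL = "near_vision_fail"


# Canonical emission order for reason codes (deterministic output).
_REASON_ORDER = tuple(ReferralReason)


@dataclass(frozen=True)
class AlgorithmVersion:
    """One iteration of the referral rule set.

    ``symptom_questions`` lists the questions this version asks of ages 6+;
    ``distance_va_mandatory`` demands both eyes' acuities (age 6+) and treats
    their absence as an error rather than a non-trigger;
    ``near_vision_required_40plus`` adds the N8 reading test for ages 40+.
    """

    iteration: int
    problem_question_scope: ProblemScope
    symptom_questions: frozenset[SymptomQuestion]
    distance_va_mandatory: bool
    near_vision_required_40plus: bool = False
    va_threshold: VisualAcuity = DEFAULT_VA_THRESHOLD

    def __post_init__(self) -> None:
        if not 1 <= self.iteration <= 7:
            raise ValueError(f"iteration must be 1-7, got {self.iteration}")

    def with_threshold(self, threshold: VisualAcuity) -> "AlgorithmVersion":
        """A copy of this version with an overridden acuity threshold."""
        return replace(self, va_threshold=threshold)


@dataclass(frozen=True)
class ReferralDecision:
    """Automated refer / do-not-refer decision with its trigger reasons."""

    refer: bool
    reasons: tuple[ReferralReason, ...]

    def __post_init__(self) -> None:
        assert self.refer == bool(self.reasons)


def _require(condition: bool, record: ParticipantRecord,
             fieldname: str, version: AlgorithmVersion) -> None:
    if not condition:
        raise DecisionError(
            f"record {record.id}: field {fieldname!r} is required by "
            f"iteration {version.iteration} but is missing/not applicable"
        )


def decide(participant: ParticipantRecord, version: AlgorithmVersion) -> ReferralDecision:
    """Apply one algorithm iteration to one participant.

    Returns the referral decision with every triggered criterion listed in
    canonical order.  Missing mandatory fields raise :class:`DecisionError`
    naming the field and iteration; nothing is silently defaulted.
    """
    reasons: set[ReferralReason] = set()

    if participant.is_child:
        # Under-6s are decided solely by the guardian's report, uniformly
        # across iterations.
        _require(participant.child_problem_reported is not TriState.NA,
                 participant, "child_problem_reported", version)
        if participant.child_problem_reported is TriState.YES:
            reasons.add(ReferralReason.CHILD_PROBLEM)
        ordered = tuple(r for r in _REASON_ORDER if r in reasons)
        return ReferralDecision(bool(ordered), ordered)

    if SymptomQuestion.ANY_EYE_PROBLEM in version.symptom_questions:
        _require(participant.any_eye_problem is not TriState.NA,
                 participant, "any_eye_problem", version)
        if participant.any_eye_problem is TriState.YES:
            reasons.add(ReferralReason.ANY_EYE_PROBLEM)

    asks_pain = (SymptomQuestion.EYE_PAIN in version.symptom_questions
                 or SymptomQuestion.EYE_PAIN_OR_DISCOMFORT in version.symptom_questions)
    if asks_pain:
        _require(participant.pain_or_discomfort is not TriState.NA,
                 participant, "pain_or_discomfort", version)
        if participant.pain_or_discomfort is TriState.YES:
            reasons.add(ReferralReason.PAIN_OR_DISCOMFORT)

    if SymptomQuestion.VISION_DIFFICULTY in version.symptom_questions:
        _require(participant.vision_difficulty is not TriState.NA,
                 participant, "vision_difficulty", version)
        if participant.vision_difficulty is TriState.YES:
            reasons.add(ReferralReason.VISION_DIFFICULTY)

    if version.distance_va_mandatory:
        _require(participant.va_right is not None, participant, "va_right", version)
        _require(participant.va_left is not None, participant, "va_left", version)
    for va in (participant.va_right, participant.va_left):
        # When acuity is optional (iterations 1-2) it is consulted only if
        # measured; absence is neither an error nor a trigger.
        if va is not None and worse_than(va, version.va_threshold):
            reasons.add(ReferralReason.LOW_DISTANCE_VA)

    if version.near_vision_required_40plus and participant.age_years >= NEAR_VISION_AGE:
        _require(participant.near_vision_n8_pass is not NearVisionResult.NA,
                 participant, "near_vision_n8_pass", version)
        if participant.near_vision_n8_pass is NearVisionResult.FAIL:
            reasons.add(ReferralReason.NEAR_VISION_FAIL)

    ordered = tuple(r for r in _REASON_ORDER if r in reasons)
    return ReferralDecision(bool(ordered), ordered)


def catalog() -> tuple[AlgorithmVersion, ...]:
    """The seven algorithm iterations, in development order.

    1. Hospital, enriched sample: "any eye problem" (no time limit), distance
       acuity optional.
    2. Community outreach, same rules as 1.
    3. Mandatory distance acuity introduced.
    4. "Any eye problem" restricted to today.
    5. Catch-all question replaced by eye pain + vision difficulty.
    6. Pain question broadened to pain or discomfort.
    7. Final: as 6, plus mandatory N8 near vision for ages 40+.
    """
    q = SymptomQuestion
    return (
        AlgorithmVersion(1, ProblemScope.ANY_DURATION,
                         frozenset({q.ANY_EYE_PROBLEM}), distance_va_mandatory=False),
        AlgorithmVersion(2, ProblemScope.ANY_DURATION,
                         frozenset({q.ANY_EYE_PROBLEM}), distance_va_mandatory=False),
        AlgorithmVersion(3, ProblemScope.ANY_DURATION,
                         frozenset({q.ANY_EYE_PROBLEM}), distance_va_mandatory=True),
        AlgorithmVersion(4, ProblemScope.TODAY_ONLY,
                         frozenset({q.ANY_EYE_PROBLEM}), distance_va_mandatory=True),
        AlgorithmVersion(5, ProblemScope.TODAY_ONLY,
                         frozenset({q.EYE_PAIN, q.VISION_DIFFICULTY}),
                         distance_va_mandatory=True),
        AlgorithmVersion(6, ProblemScope.TODAY_ONLY,
                         frozenset({q.EYE_PAIN_OR_DISCOMFORT, q.VISION_DIFFICULTY}),
                         distance_va_mandatory=True),
        AlgorithmVersion(7, ProblemScope.TODAY_ONLY,
                         frozenset({q.EYE_PAIN_OR_DISCOMFORT, q.VISION_DIFFICULTY}),
                         distance_va_mandatory=True, near_vision_required_40plus=True),
    )


def get_version(iteration: int) -> AlgorithmVersion:
    """Look up one iteration (1-7) from :func:`catalog`."""
    versions = catalog()
    if not 1 <= iteration <= len(versions):
        raise ValueError(f"iteration must be 1-{len(versions)}, got {iteration}")
    return versions[iteration - 1]
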