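"""Participant records for community eye screening.

One record is one screened person: demographics, the answers elicited by the
screener (community volunteer, CV), per-eye distance acuity, near vision, and
the reference-standard diagnosis and referral decision made by an ophthalmic
clinical officer (OCO) on the same person.

Question answers are tri-state (:class:`TriState`) rather than boolean so
"question not applicable / not asked under this algorithm version" is
representable and auditable: the child-problem question only applies under
age 6, distance acuity is only measured from age 6, and near vision (reading
N8 print at 33 cm) is only assessed from age 40.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Mapping

from .acuity import VisualAcuity

__all__ = [
    "TriState",
    "NearVisionResult",
    "Sex",
    "Diagnosis",
    "ParticipantRecord",
    "RecordError",
    "NEAR_VISION_AGE",
    "CHILD_AGE_LIMIT",
]

#: Children strictly younger than this are assessed only via the guardian question.
CHILD_AGE_LIMIT = 6
#: Near-vision (N8 at 33 cm) assessment applies from this age (inclusive).
NEAR_VISION_AGE = 40


class RecordError(ValueError):
    """A participant record violates its invariants."""


class TriState(str, enum.Enum):
    """Answer to a screening question: yes, no, or not applicable/not asked."""

    YES = "yes"
    NO = "no"
    NA = "NA"


class NearVisionResult(str, enum.Enum):
    """Outcome of the N8 near-vision assessment at 33 cm."""

    PASS = "pass"
    FAIL = "fail"
    NA = "NA"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Diagnosis(str, enum.Enum):
    """Reference diagnosis groups (Kenyan MoH classification, grouped)."""

    NORMAL = "normal"
    CATARACT = "cataract"
    PRESBYOPIA = "presbyopia"
    GLAUCOMA = "glaucoma"
    REFRACTIVE_ERROR = "refractive_error"
    ALLERGIC_CONJUNCTIVITIS = "allergic_conjunctivitis"
    OTHER_CONJUNCTIVITIS = "other_conjunctivitis"
    CORNEAL_DISEASE = "corneal_disease"
    RETINAL_DISEASE = "retinal_disease"
    EYE_INJURY_FOREIGN_BODY = "eye_injury_foreign_body"
    UVEITIS = "uveitis"
    PTERYGIUM_GROWTHS = "pterygium_growths"
    LID_DISEASE = "lid_disease"
    OTHER = "other"


#: Raw Kenyan MoH labels mapped onto the grouped diagnoses above.
MOH_LABEL_GROUPS: Mapping[str, Diagnosis] = {
    "normal": Diagnosis.NORMAL,
    "cataract": Diagnosis.CATARACT,
    "corneal scars": Diagnosis.CORNEAL_DISEASE,
    "conjunctivitis": Diagnosis.OTHER_CONJUNCTIVITIS,
    "keratitis": Diagnosis.CORNEAL_DISEASE,
    "uveitis": Diagnosis.UVEITIS,
    "retinal disease": Diagnosis.RETINAL_DISEASE,
    "eyelid disease": Diagnosis.LID_DISEASE,
    "presbyopia": Diagnosis.PRESBYOPIA,
    "other refractive error": Diagnosis.REFRACTIVE_ERROR,
    "foreign body": Diagnosis.EYE_INJURY_FOREIGN_BODY,
    "eye growths": Diagnosis.PTERYGIUM_GROWTHS,
    "eye injury": Diagnosis.EYE_INJURY_FOREIGN_BODY,
    "other": Diagnosis.OTHER,
}


@dataclass(frozen=True)
class ParticipantRecord:
    """One screened participant.

    ``child_problem_reported`` answers "Does the child have any problem with
    their eyes today?" (guardian, under-6s only).  ``pain_or_discomfort`` and
    ``vision_difficulty`` answer the adult symptom questions; which pain
    question they answer (pain only vs pain-or-discomfort) is a property of
    the algorithm version the data were collected under.
    ``any_eye_problem`` answers the early-iteration catch-all question
    ("any eye problem", duration scoped by the version).

    ``latent`` optionally carries simulator ground truth (reference-interview
    answers, true acuity) and is never consulted by the decision engine.
    """

    id: str
    age_years: int
    sex: Sex
    child_problem_reported: TriState = TriState.NA
    pain_or_discomfort: TriState = TriState.NA
    vision_difficulty: TriState = TriState.NA
    any_eye_problem: TriState = TriState.NA
    va_right: VisualAcuity | None = None
    va_left: VisualAcuity | None = None
    near_vision_n8_pass: NearVisionResult = NearVisionResult.NA
    reference_diagnosis: Diagnosis | None = None
    reference_referral: bool | None = None
    latent: Mapping[str, Any] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.age_years, int) or self.age_years < 0:
            raise RecordError(f"record {self.id}: age_years must be a non-negative "
                              f"integer, got {self.age_years!r}")
        if self.is_child:
            if self.va_right is not None or self.va_left is not None:
                raise RecordError(f"record {self.id}: distance acuity must not be "
                                  f"recorded for a child aged {self.age_years}")
        else:
            if self.child_problem_reported is not TriState.NA:
                raise RecordError(f"record {self.id}: child_problem_reported only "
                                  f"applies under age {CHILD_AGE_LIMIT}")
        if self.age_years < NEAR_VISION_AGE and self.near_vision_n8_pass is not NearVisionResult.NA:
            raise RecordError(f"record {self.id}: near vision only assessed from "
                              f"age {NEAR_VISION_AGE}")

    @property
    def is_child(self) -> bool:
        return self.age_years < CHILD_AGE_LIMIT

    @property
    def better_eye(self) -> VisualAcuity | None:
        """The better (lower-logMAR) of the two assessed eyes, if any."""
        eyes = [va for va in (self.va_right, self.va_left) if va is not None]
        return min(eyes, key=lambda v: v.logmar) if eyes else None
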