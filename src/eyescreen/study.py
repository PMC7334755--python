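"""Published counts from the Trans Nzoia community eye-screening validation.

These tables are the study's printed results, kept here as structured inputs:
the seven per-iteration 2x2 referral tables, the interrater marginals from
the CV training exercise, the participant-flow counts, the demographic and
acuity-band composition of the final validation sample, and the diagnosis
breakdown of the reference-referred participants by index decision.
"""

from __future__ import annotations

from types import MappingProxyType

from .records import Diagnosis
from .stats import ConfusionTable

__all__ = [
    "ITERATION_TABLES",
    "ITERATION_SETTINGS",
    "INTERRATER",
    "FLOW_ELIGIBLE",
    "FLOW_ANALYZED",
    "AGE_GROUP_COUNTS",
    "SEX_COUNTS",
    "ACUITY_BAND_COUNTS",
    "REFERRED_DIAGNOSIS_COUNTS",
    "SAMPLE_SIZE_DESIGN",
]

#: Reference-vs-index referral tables for iterations 1-7 (tp, fn, fp, tn).
ITERATION_TABLES: dict[int, ConfusionTable] = MappingProxyType({
    1: ConfusionTable(tp=117, fn=1, fp=10, tn=11),
    2: ConfusionTable(tp=250, fn=3, fp=18, tn=35),
    3: ConfusionTable(tp=110, fn=3, fp=74, tn=16),
    4: ConfusionTable(tp=182, fn=50, fp=32, tn=99),
    5: ConfusionTable(tp=144, fn=28, fp=54, tn=85),
    6: ConfusionTable(tp=342, fn=36, fp=102, tn=176),
    7: ConfusionTable(tp=344, fn=34, fp=43, tn=153),
})

ITERATION_SETTINGS: dict[int, str] = MappingProxyType({
    1: "hospital (enriched sample)",
    2: "community (enriched sample)",
    3: "community", 4: "community", 5: "community",
    6: "community", 7: "community (final algorithm)",
})

#: CV training exercise: n participants, reference-positive count, each
#: trainee's positive count and raw percent agreement with the reference.
INTERRATER = MappingProxyType({
    "n": 59,
    "reference_pos": 44,
    "cv1": {"pos": 49, "agreement": 0.848},
    "cv2": {"pos": 50, "agreement": 0.864},
})

#: Participant flow of the final validation round.
FLOW_ELIGIBLE = 607
FLOW_ANALYZED = 574

#: Final-round sample composition (counts out of 574).
AGE_GROUP_COUNTS: dict[str, int] = MappingProxyType({
    "<15": 252, "15-29": 100, "30-44": 80, "45-59": 76, "60-74": 52, "75+": 14,
})
SEX_COUNTS: dict[str, int] = MappingProxyType({"male": 213, "female": 361})
ACUITY_BAND_COUNTS: dict[str, int] = MappingProxyType({
    "not_assessed": 82, "6/6-6/12": 411, "6/18-6/60": 59, "<6/60": 22,
})

#: Reference-referred participants by diagnosis group: (index referred,
#: index missed i.e. false negatives).  Columns sum to 344 and 34.
REFERRED_DIAGNOSIS_COUNTS: dict[Diagnosis, tuple[int, int]] = MappingProxyType({
    Diagnosis.CATARACT: (29, 0),
    Diagnosis.PRESBYOPIA: (56, 2),
    Diagnosis.GLAUCOMA: (1, 1),
    Diagnosis.REFRACTIVE_ERROR: (64, 2),
    Diagnosis.ALLERGIC_CONJUNCTIVITIS: (117, 16),
    Diagnosis.OTHER_CONJUNCTIVITIS: (44, 9),
    Diagnosis.CORNEAL_DISEASE: (2, 0),
    Diagnosis.RETINAL_DISEASE: (5, 0),
    Diagnosis.EYE_INJURY_FOREIGN_BODY: (1, 0),
    Diagnosis.UVEITIS: (1, 0),
    Diagnosis.PTERYGIUM_GROWTHS: (10, 0),
    Diagnosis.LID_DISEASE: (2, 0),
    Diagnosis.OTHER: (12, 4),
})

#: The study's precision design for the final round: target sensitivity,
#: half-width, and assumed referable prevalence.
SAMPLE_SIZE_DESIGN = MappingProxyType({
    "target_sens": 0.90, "half_width": 0.05, "prevalence": 0.30,
})
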