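"""Synthetic community screening populations.

Generates participant records with the statistical structure of a community
eye-screening sample: the age/sex composition and acuity-band mix of the
validation round, a diagnosis mix whose referable part matches the observed
diagnosis breakdown, and a configurable referable prevalence (default 65.9%).

The generative process per person is:

1. draw age group (then an integer age uniform within the group) and sex;
2. draw a diagnosis from ``diagnosis_mix``; draw whether the reference
   standard refers from ``referable_given_diagnosis[diagnosis]``;
3. draw the *reference interview* answers (pain/discomfort, vision
   difficulty, catch-all problem questions, guardian report for under-6s)
   from per-diagnosis Bernoulli probabilities, a better-eye acuity band from
   the per-diagnosis band distribution (uniform over the band's discrete
   Snellen lines within it), and the N8 near-vision result for ages 40+;
4. derive the *screener-observed* (CV) fields by passing every answer
   through a symmetric flip channel with probability
   ``cv_noise.symptom_flip_prob`` and adding Gaussian test-retest noise of
   ``cv_noise.acuity_logmar_sd`` logMAR to each eye's acuity before snapping
   back to the nearest chart line.

The per-diagnosis probabilities are calibration targets chosen to reproduce
the study-level margins, not epidemiological estimates for any real
population.  One integer seed drives a single numpy Generator stream;
identical seeds give identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .acuity import SNELLEN_LINES, VisualAcuity, parse_snellen
from .decision import ProblemScope, decide, get_version
from .records import (
    CHILD_AGE_LIMIT,
    NEAR_VISION_AGE,
    Diagnosis,
    NearVisionResult,
    ParticipantRecord,
    Sex,
    TriState,
)
from .study import AGE_GROUP_COUNTS, REFERRED_DIAGNOSIS_COUNTS, SEX_COUNTS

__all__ = [
    "SymptomProfile",
    "CVNoise",
    "PopulationModel",
    "default_model",
    "simulate",
    "reference_view",
    "write_fixture",
    "AGE_GROUP_BOUNDS",
    "ACUITY_BAND_LINES",
]

#: Integer age ranges (inclusive) for the reporting age groups.
AGE_GROUP_BOUNDS: dict[str, tuple[int, int]] = {
    "<15": (0, 14), "15-29": (15, 29), "30-44": (30, 44),
    "45-59": (45, 59), "60-74": (60, 74), "75+": (75, 90),
}

#: Discrete Snellen lines of each better-eye acuity band.
ACUITY_BAND_LINES: dict[str, tuple[str, ...]] = {
    "normal": ("6/6", "6/9", "6/12"),
    "impaired": ("6/18", "6/24", "6/36", "6/60"),
    "severe": ("3/60", "2/60", "1/60"),
}

_LINE_ACUITIES = tuple(parse_snellen(s) for s in SNELLEN_LINES)
_LINE_LOGMARS = np.array([a.logmar for a in _LINE_ACUITIES])


@dataclass(frozen=True)
class SymptomProfile:
    """Reference-interview answer probabilities for one diagnosis.

    ``pain``/``vision_difficulty`` drive the final-algorithm questions;
    ``any_problem`` (unlimited duration) and ``problem_today`` drive the
    early-iteration catch-all question; ``child_problem`` is the guardian's
    report for under-6s.
    """

    pain: float
    vision_difficulty: float
    child_problem: float
    any_problem: float
    problem_today: float


@dataclass(frozen=True)
class CVNoise:
    """Measurement-error channel between reference truth and the screener.

    ``symptom_flip_prob``: probability each elicited answer (including the
    near-vision result) flips relative to the reference interview.
    ``acuity_logmar_sd``: SD of Gaussian test-retest noise added to each
    eye's logMAR before snapping to the nearest chart line.
    """

    symptom_flip_prob: float = 0.03
    acuity_logmar_sd: float = 0.05


@dataclass(frozen=True)
class PopulationModel:
    """Generative parameters for a synthetic screening population."""

    age_group_weights: Mapping[str, float]
    sex_female: float
    diagnosis_mix: Mapping[Diagnosis, float]
    referable_given_diagnosis: Mapping[Diagnosis, float]
    symptom_model: Mapping[Diagnosis, SymptomProfile]
    acuity_model: Mapping[Diagnosis, tuple[float, float, float]]
    near_vision_fail_rate: Mapping[Diagnosis, float]
    cv_noise: CVNoise = field(default_factory=CVNoise)

    def validate(self) -> None:
        """Check the model invariants; raise ValueError on violation."""
        def check_simplex(name: str, weights: Mapping) -> None:
            total = float(sum(weights.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total!r}")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} has a negative weight")

        check_simplex("age_group_weights", self.age_group_weights)
        check_simplex("diagnosis_mix", self.diagnosis_mix)
        if set(self.age_group_weights) != set(AGE_GROUP_BOUNDS):
            raise ValueError("age_group_weights must cover exactly the six age groups")
        probs = [self.sex_female, self.cv_noise.symptom_flip_prob]
        probs += list(self.referable_given_diagnosis.values())
        probs += list(self.near_vision_fail_rate.values())
        for prof in self.symptom_model.values():
            probs += [prof.pain, prof.vision_difficulty, prof.child_problem,
                      prof.any_problem, prof.problem_today]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.cv_noise.acuity_logmar_sd < 0:
            raise ValueError("acuity_logmar_sd must be non-negative")
        for d, bands in self.acuity_model.items():
            if len(bands) != 3 or abs(sum(bands) - 1.0) > 1e-9 or min(bands) < 0:
                raise ValueError(f"acuity band weights for {d.value} must be a "
                                 f"3-simplex, got {bands}")
        for d in self.diagnosis_mix:
            for mapping, name in ((self.referable_given_diagnosis, "referable"),
                                  (self.symptom_model, "symptom"),
                                  (self.acuity_model, "acuity"),
                                  (self.near_vision_fail_rate, "near-vision")):
                if d not in mapping:
                    raise ValueError(f"no {name} parameters for diagnosis {d.value}")

    @property
    def expected_referable_prevalence(self) -> float:
        """sum_d P(diagnosis=d) P(refer | d) under the model."""
        return float(sum(self.diagnosis_mix[d] * self.referable_given_diagnosis[d]
                         for d in self.diagnosis_mix))

    def replace(self, **changes) -> "PopulationModel":
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_config(self) -> dict:
        return {
            "age_group_weights": dict(self.age_group_weights),
            "sex_female": self.sex_female,
            "diagnosis_mix": {d.value: w for d, w in self.diagnosis_mix.items()},
            "referable_given_diagnosis": {
                d.value: p for d, p in self.referable_given_diagnosis.items()},
            "symptom_model": {d.value: dataclasses.asdict(p)
                              for d, p in self.symptom_model.items()},
            "acuity_model": {d.value: list(b) for d, b in self.acuity_model.items()},
            "near_vision_fail_rate": {
                d.value: p for d, p in self.near_vision_fail_rate.items()},
            "cv_noise": dataclasses.asdict(self.cv_noise),
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "PopulationModel":
        model = cls(
            age_group_weights=dict(cfg["age_group_weights"]),
            sex_female=float(cfg["sex_female"]),
            diagnosis_mix={Diagnosis(k): float(v)
                           for k, v in cfg["diagnosis_mix"].items()},
            referable_given_diagnosis={
                Diagnosis(k): float(v)
                for k, v in cfg["referable_given_diagnosis"].items()},
            symptom_model={Diagnosis(k): SymptomProfile(**v)
                           for k, v in cfg["symptom_model"].items()},
            acuity_model={Diagnosis(k): tuple(v)
                          for k, v in cfg["acuity_model"].items()},
            near_vision_fail_rate={
                Diagnosis(k): float(v)
                for k, v in cfg["near_vision_fail_rate"].items()},
            cv_noise=CVNoise(**cfg.get("cv_noise", {})),
        )
        model.validate()
        return model

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_config(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PopulationModel":
        return cls.from_config(json.loads(Path(path).read_text()))


# Per-diagnosis defaults.  Symptom probabilities are set so that ocular
# surface inflammation (conjunctivitis) is symptom-driven and dominates
# misses, while media/retina/refractive disease is vision-driven; the
# catch-all "any problem ever" question is deliberately near-useless in
# healthy people (high yes-rate), reproducing the early iterations' poor
# specificity when the question was unscoped.
_PROFILES: dict[Diagnosis, SymptomProfile] = {
    Diagnosis.NORMAL: SymptomProfile(0.05, 0.05, 0.08, 0.75, 0.20),
    Diagnosis.CATARACT: SymptomProfile(0.05, 0.95, 0.90, 0.95, 0.85),
    Diagnosis.PRESBYOPIA: SymptomProfile(0.10, 0.95, 0.90, 0.95, 0.80),
    Diagnosis.GLAUCOMA: SymptomProfile(0.30, 0.60, 0.90, 0.95, 0.70),
    Diagnosis.REFRACTIVE_ERROR: SymptomProfile(0.10, 0.95, 0.90, 0.95, 0.80),
    Diagnosis.ALLERGIC_CONJUNCTIVITIS: SymptomProfile(0.85, 0.30, 0.85, 0.95, 0.90),
    Diagnosis.OTHER_CONJUNCTIVITIS: SymptomProfile(0.85, 0.30, 0.85, 0.95, 0.90),
    Diagnosis.CORNEAL_DISEASE: SymptomProfile(0.80, 0.60, 0.90, 0.95, 0.85),
    Diagnosis.RETINAL_DISEASE: SymptomProfile(0.05, 0.90, 0.90, 0.90, 0.70),
    Diagnosis.EYE_INJURY_FOREIGN_BODY: SymptomProfile(0.90, 0.30, 0.95, 0.95, 0.95),
    Diagnosis.UVEITIS: SymptomProfile(0.90, 0.50, 0.90, 0.95, 0.90),
    Diagnosis.PTERYGIUM_GROWTHS: SymptomProfile(0.50, 0.20, 0.85, 0.90, 0.60),
    Diagnosis.LID_DISEASE: SymptomProfile(0.60, 0.10, 0.90, 0.90, 0.75),
    Diagnosis.OTHER: SymptomProfile(0.50, 0.40, 0.85, 0.90, 0.70),
}

_ACUITY_BANDS: dict[Diagnosis, tuple[float, float, float]] = {
    Diagnosis.NORMAL: (1.00, 0.00, 0.00),
    Diagnosis.CATARACT: (0.30, 0.50, 0.20),
    Diagnosis.PRESBYOPIA: (0.90, 0.10, 0.00),
    Diagnosis.GLAUCOMA: (0.50, 0.30, 0.20),
    Diagnosis.REFRACTIVE_ERROR: (0.50, 0.45, 0.05),
    Diagnosis.ALLERGIC_CONJUNCTIVITIS: (0.92, 0.08, 0.00),
    Diagnosis.OTHER_CONJUNCTIVITIS: (0.90, 0.10, 0.00),
    Diagnosis.CORNEAL_DISEASE: (0.40, 0.40, 0.20),
    Diagnosis.RETINAL_DISEASE: (0.30, 0.40, 0.30),
    Diagnosis.EYE_INJURY_FOREIGN_BODY: (0.60, 0.30, 0.10),
    Diagnosis.UVEITIS: (0.50, 0.40, 0.10),
    Diagnosis.PTERYGIUM_GROWTHS: (0.85, 0.15, 0.00),
    Diagnosis.LID_DISEASE: (0.95, 0.05, 0.00),
    Diagnosis.OTHER: (0.80, 0.15, 0.05),
}

_NEAR_FAIL: dict[Diagnosis, float] = {
    Diagnosis.NORMAL: 0.10,
    Diagnosis.CATARACT: 0.60,
    Diagnosis.PRESBYOPIA: 0.95,
    Diagnosis.GLAUCOMA: 0.40,
    Diagnosis.REFRACTIVE_ERROR: 0.50,
    Diagnosis.ALLERGIC_CONJUNCTIVITIS: 0.20,
    Diagnosis.OTHER_CONJUNCTIVITIS: 0.20,
    Diagnosis.CORNEAL_DISEASE: 0.40,
    Diagnosis.RETINAL_DISEASE: 0.50,
    Diagnosis.EYE_INJURY_FOREIGN_BODY: 0.20,
    Diagnosis.UVEITIS: 0.30,
    Diagnosis.PTERYGIUM_GROWTHS: 0.20,
    Diagnosis.LID_DISEASE: 0.15,
    Diagnosis.OTHER: 0.30,
}

_REFERABLE: dict[Diagnosis, float] = {
    Diagnosis.NORMAL: 0.0,
    Diagnosis.CATARACT: 1.0,
    Diagnosis.PRESBYOPIA: 0.95,
    Diagnosis.GLAUCOMA: 1.0,
    Diagnosis.REFRACTIVE_ERROR: 0.95,
    Diagnosis.ALLERGIC_CONJUNCTIVITIS: 0.85,
    Diagnosis.OTHER_CONJUNCTIVITIS: 0.85,
    Diagnosis.CORNEAL_DISEASE: 1.0,
    Diagnosis.RETINAL_DISEASE: 1.0,
    Diagnosis.EYE_INJURY_FOREIGN_BODY: 1.0,
    Diagnosis.UVEITIS: 1.0,
    Diagnosis.PTERYGIUM_GROWTHS: 0.90,
    Diagnosis.LID_DISEASE: 0.90,
    Diagnosis.OTHER: 0.90,
}


def default_model(target_prevalence: float = 0.659,
                  cv_noise: CVNoise | None = None) -> PopulationModel:
    """The default population model, calibrated to the validation round.

    Age-group and sex weights are the observed sample proportions.  The
    diagnosis mix is solved from the observed diagnosis breakdown of the
    referable participants: with referral probabilities r_d fixed,
    ``P(d) = prevalence * share_d / r_d`` makes the referable-conditional
    diagnosis distribution match the observed shares exactly and the overall
    expected referable prevalence equal ``target_prevalence``; the remaining
    mass is "normal".
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError(f"target_prevalence must be in (0,1), got {target_prevalence}")
    total_age = sum(AGE_GROUP_COUNTS.values())
    age_weights = {g: c / total_age for g, c in AGE_GROUP_COUNTS.items()}
    sex_female = SEX_COUNTS["female"] / (SEX_COUNTS["male"] + SEX_COUNTS["female"])

    referred_total = sum(ref + fn for ref, fn in REFERRED_DIAGNOSIS_COUNTS.values())
    mix: dict[Diagnosis, float] = {}
    for d, (ref, fn) in REFERRED_DIAGNOSIS_COUNTS.items():
        share = (ref + fn) / referred_total
        mix[d] = target_prevalence * share / _REFERABLE[d]
    normal_mass = 1.0 - sum(mix.values())
    if normal_mass < 0:
        raise ValueError("target prevalence too high for the referral probabilities")
    mix[Diagnosis.NORMAL] = normal_mass

    model = PopulationModel(
        age_group_weights=age_weights,
        sex_female=sex_female,
        diagnosis_mix=mix,
        referable_given_diagnosis=dict(_REFERABLE),
        symptom_model=dict(_PROFILES),
        acuity_model=dict(_ACUITY_BANDS),
        near_vision_fail_rate=dict(_NEAR_FAIL),
        cv_noise=cv_noise or CVNoise(),
    )
    model.validate()
    return model


def _snap_to_line(logmar: float) -> VisualAcuity:
    """Nearest discrete Snellen chart line to a (noisy) logMAR value."""
    idx = int(np.argmin(np.abs(_LINE_LOGMARS - logmar)))
    return _LINE_ACUITIES[idx]


def _flip(answer: bool, p: float, rng: np.random.Generator) -> bool:
    return (not answer) if (p > 0 and rng.random() < p) else answer


def _tri(answer: bool) -> TriState:
    return TriState.YES if answer else TriState.NO


def simulate(model: PopulationModel, n: int, seed: int,
             problem_scope: ProblemScope = ProblemScope.ANY_DURATION,
             reference_rule: int | None = None) -> list[ParticipantRecord]:
    """Draw ``n`` synthetic participants from ``model``.

    ``problem_scope`` selects which catch-all question the record's
    ``any_eye_problem`` field answers (unlimited duration vs today only),
    i.e. which early iteration the data were "collected under".

    ``reference_rule`` switches the reference standard: ``None`` (default)
    generates the reference referral from the latent diagnosis via
    ``referable_given_diagnosis``; an iteration number 1-7 instead sets it
    to that rule applied to the *reference-interview* fields, giving a
    decision-consistent reference (with zero CV noise, index and reference
    then agree perfectly).

    Records carry the screener-observed fields; the reference truth is kept
    under ``record.latent``.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    model.validate()
    rng = np.random.default_rng(seed)

    groups = list(model.age_group_weights)
    group_w = np.array([model.age_group_weights[g] for g in groups])
    diagnoses = list(model.diagnosis_mix)
    diag_w = np.array([model.diagnosis_mix[d] for d in diagnoses])
    band_names = ("normal", "impaired", "severe")
    flip_p = model.cv_noise.symptom_flip_prob
    acuity_sd = model.cv_noise.acuity_logmar_sd

    records: list[ParticipantRecord] = []
    for i in range(n):
        group = groups[rng.choice(len(groups), p=group_w)]
        lo, hi = AGE_GROUP_BOUNDS[group]
        age = int(rng.integers(lo, hi + 1))
        sex = Sex.FEMALE if rng.random() < model.sex_female else Sex.MALE
        diagnosis = diagnoses[rng.choice(len(diagnoses), p=diag_w)]
        profile = model.symptom_model[diagnosis]
        is_child = age < CHILD_AGE_LIMIT

        # Reference-interview truth.
        ref = {
            "pain": rng.random() < profile.pain,
            "vision_difficulty": rng.random() < profile.vision_difficulty,
            "any_problem": rng.random() < profile.any_problem,
            "problem_today": rng.random() < profile.problem_today,
            "child_problem": rng.random() < profile.child_problem,
        }
        band = band_names[rng.choice(3, p=np.array(model.acuity_model[diagnosis]))]
        lines = ACUITY_BAND_LINES[band]
        better = parse_snellen(lines[rng.integers(len(lines))])
        # The band classifies the person, so both eyes stay inside it: the
        # worse eye sits 0 or 1 chart lines below the better one, clamped to
        # the band's last line.
        better_idx = SNELLEN_LINES.index(str(better))
        band_last_idx = SNELLEN_LINES.index(lines[-1])
        offset = 1 if rng.random() < 0.3 else 0
        worse_idx = min(better_idx + offset, band_last_idx)
        worse = _LINE_ACUITIES[worse_idx]
        right_better = bool(rng.random() < 0.5)
        ref_va_r, ref_va_l = (better, worse) if right_better else (worse, better)
        ref["near_fail"] = (age >= NEAR_VISION_AGE
                            and rng.random() < model.near_vision_fail_rate[diagnosis])
        ref["va_right"], ref["va_left"] = (
            (None, None) if is_child else (ref_va_r, ref_va_l))
        ref["acuity_band"] = None if is_child else band
        referable = bool(rng.random() < model.referable_given_diagnosis[diagnosis])

        # Screener-observed (CV) fields: flip channel + acuity noise.
        cv_pain = _flip(ref["pain"], flip_p, rng)
        cv_vd = _flip(ref["vision_difficulty"], flip_p, rng)
        scoped = (ref["any_problem"] if problem_scope is ProblemScope.ANY_DURATION
                  else ref["problem_today"])
        cv_any = _flip(scoped, flip_p, rng)
        cv_child = _flip(ref["child_problem"], flip_p, rng)
        cv_near = _flip(ref["near_fail"], flip_p, rng)
        if is_child:
            cv_va_r = cv_va_l = None
        elif acuity_sd > 0:
            cv_va_r = _snap_to_line(ref_va_r.logmar + rng.normal(0.0, acuity_sd))
            cv_va_l = _snap_to_line(ref_va_l.logmar + rng.normal(0.0, acuity_sd))
        else:
            cv_va_r, cv_va_l = ref_va_r, ref_va_l

        if reference_rule is None:
            reference_referral = referable
        else:
            ref_record = ParticipantRecord(
                id=f"ref-{i}", age_years=age, sex=sex,
                child_problem_reported=_tri(ref["child_problem"]) if is_child else TriState.NA,
                pain_or_discomfort=TriState.NA if is_child else _tri(ref["pain"]),
                vision_difficulty=TriState.NA if is_child else _tri(ref["vision_difficulty"]),
                any_eye_problem=TriState.NA if is_child else _tri(scoped),
                va_right=ref["va_right"], va_left=ref["va_left"],
                near_vision_n8_pass=(
                    (NearVisionResult.FAIL if ref["near_fail"] else NearVisionResult.PASS)
                    if age >= NEAR_VISION_AGE else NearVisionResult.NA),
                reference_diagnosis=diagnosis,
            )
            reference_referral = decide(ref_record, get_version(reference_rule)).refer

        records.append(ParticipantRecord(
            id=f"sim-{i:06d}",
            age_years=age,
            sex=sex,
            child_problem_reported=_tri(cv_child) if is_child else TriState.NA,
            pain_or_discomfort=TriState.NA if is_child else _tri(cv_pain),
            vision_difficulty=TriState.NA if is_child else _tri(cv_vd),
            any_eye_problem=TriState.NA if is_child else _tri(cv_any),
            va_right=cv_va_r,
            va_left=cv_va_l,
            near_vision_n8_pass=(
                (NearVisionResult.FAIL if cv_near else NearVisionResult.PASS)
                if age >= NEAR_VISION_AGE else NearVisionResult.NA),
            reference_diagnosis=diagnosis,
            reference_referral=reference_referral,
            latent={**ref, "diagnosis": diagnosis, "referable": referable,
                    "age_group": group, "problem_scope": problem_scope.value},
        ))
    return records


def reference_view(record: ParticipantRecord) -> ParticipantRecord:
    """Rebuild a simulated record as the reference interview saw it.

    Requires the simulator's ``latent`` payload; useful for noise-channel
    analyses (index decisions from reference truth vs screener observation).
    """
    if record.latent is None:
        raise ValueError(f"record {record.id} carries no latent truth")
    lat = record.latent
    is_child = record.is_child
    scoped = (lat["any_problem"]
              if lat.get("problem_scope") == ProblemScope.ANY_DURATION.value
              else lat["problem_today"])
    return ParticipantRecord(
        id=record.id, age_years=record.age_years, sex=record.sex,
        child_problem_reported=_tri(lat["child_problem"]) if is_child else TriState.NA,
        pain_or_discomfort=TriState.NA if is_child else _tri(lat["pain"]),
        vision_difficulty=TriState.NA if is_child else _tri(lat["vision_difficulty"]),
        any_eye_problem=TriState.NA if is_child else _tri(scoped),
        va_right=lat["va_right"], va_left=lat["va_left"],
        near_vision_n8_pass=(
            (NearVisionResult.FAIL if lat["near_fail"] else NearVisionResult.PASS)
            if record.age_years >= NEAR_VISION_AGE else NearVisionResult.NA),
        reference_diagnosis=record.reference_diagnosis,
        reference_referral=record.reference_referral,
        latent=lat,
    )


def write_fixture(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write records as a participant CSV (see :mod:`eyescreen.io`)."""
    from .io import write_participants

    write_participants(records, path)
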