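"""Shared fixtures: canonical records, study-shaped fixtures, big simulations."""

from __future__ import annotations

import pytest
from hypothesis import settings as hyp_settings

from eyescreen import (
    ConfusionTable,
    NearVisionResult,
    ParticipantRecord,
    Sex,
    TriState,
    default_model,
    parse_snellen,
    simulate,
)
from eyescreen.study import ITERATION_TABLES

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")


def make_adult(id="a", age=30, pain="no", vd="no", any_problem="no",
               va_right="6/6", va_left="6/6", near=None,
               reference_referral=None, diagnosis=None, sex=Sex.FEMALE):
    """An adult record with sensible defaults, all fields overridable."""
    if near is None:
        near = NearVisionResult.PASS if age >= 40 else NearVisionResult.NA
    elif isinstance(near, str):
        near = NearVisionResult(near)
    return ParticipantRecord(
        id=id, age_years=age, sex=sex,
        pain_or_discomfort=TriState(pain),
        vision_difficulty=TriState(vd),
        any_eye_problem=TriState(any_problem),
        va_right=parse_snellen(va_right) if va_right else None,
        va_left=parse_snellen(va_left) if va_left else None,
        near_vision_n8_pass=near,
        reference_diagnosis=diagnosis,
        reference_referral=reference_referral,
    )


def make_child(id="c", age=4, problem="no", reference_referral=None,
               diagnosis=None):
    return ParticipantRecord(
        id=id, age_years=age, sex=Sex.MALE,
        child_problem_reported=TriState(problem),
        reference_diagnosis=diagnosis,
        reference_referral=reference_referral,
    )


def records_for_table(table: ConfusionTable) -> list[ParticipantRecord]:
    """A record set whose iteration-7 decisions reproduce a 2x2 table.

    Index-positive records carry a pain complaint; index-negative records
    are asymptomatic with normal vision.
    """
    recs = []
    for i in range(table.tp):
        recs.append(make_adult(id=f"tp{i}", pain="yes", reference_referral=True))
    for i in range(table.fn):
        recs.append(make_adult(id=f"fn{i}", reference_referral=True))
    for i in range(table.fp):
        recs.append(make_adult(id=f"fp{i}", pain="yes", reference_referral=False))
    for i in range(table.tn):
        recs.append(make_adult(id=f"tn{i}", reference_referral=False))
    return recs


@pytest.fixture(scope="session")
def final_round_records():
    """Records replaying the final validation round's 2x2 (n=574)."""
    return records_for_table(ITERATION_TABLES[7])


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def big_simulation(model):
    """One 50k-person draw from the default model, shared across tests."""
    return simulate(model, 50_000, seed=20160345)
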