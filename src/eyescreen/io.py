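"""Participant file reading and writing.

The participant file is UTF-8 comma-separated text with a mandatory header::

    id,age_years,sex,child_problem,pain_discomfort,vision_difficulty,
    va_right,va_left,near_n8,diagnosis,reference_referral

Acuities are Snellen strings ("6/12") or "NA" for not assessed (children
under 6); tri-state answers are yes/no/NA; near vision is pass/fail/NA;
reference_referral is refer/no_refer/NA.  An optional ``any_eye_problem``
column (yes/no/NA) carries the early iterations' catch-all question.  Every
row is validated against the record invariants and failures are reported
with their row number.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .acuity import AcuityParseError, VisualAcuity, parse_snellen
from .records import (
    Diagnosis,
    NearVisionResult,
    ParticipantRecord,
    RecordError,
    Sex,
    TriState,
)

__all__ = ["read_participants", "write_participants", "ParticipantFileError",
           "REQUIRED_COLUMNS"]

NA = "NA"

REQUIRED_COLUMNS = (
    "id", "age_years", "sex", "child_problem", "pain_discomfort",
    "vision_difficulty", "va_right", "va_left", "near_n8", "diagnosis",
    "reference_referral",
)
OPTIONAL_COLUMNS = ("any_eye_problem",)


class ParticipantFileError(ValueError):
    """A participant file is malformed; the message carries row context."""


def _parse_tristate(token: str, column: str, row: int) -> TriState:
    try:
        return {"yes": TriState.YES, "no": TriState.NO, NA: TriState.NA}[token]
    except KeyError:
        raise ParticipantFileError(
            f"row {row}: column {column!r} must be yes/no/NA, got {token!r}"
        ) from None


def _parse_acuity(token: str, column: str, row: int) -> VisualAcuity | None:
    if token == NA:
        return None
    try:
        return parse_snellen(token)
    except AcuityParseError as e:
        raise ParticipantFileError(f"row {row}: column {column!r}: {e}") from e


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read and validate a participant CSV file."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise ParticipantFileError(f"{path}: empty file, header row is mandatory")
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ParticipantFileError(f"{path}: missing required columns {missing}")
        unknown = [c for c in header
                   if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
        if unknown:
            raise ParticipantFileError(f"{path}: unknown columns {unknown}")

        records: list[ParticipantRecord] = []
        for rownum, row in enumerate(reader, start=2):
            try:
                age = int(row["age_years"])
            except (TypeError, ValueError):
                raise ParticipantFileError(
                    f"row {rownum}: age_years must be an integer, "
                    f"got {row['age_years']!r}") from None
            try:
                sex = Sex(row["sex"])
            except ValueError:
                raise ParticipantFileError(
                    f"row {rownum}: sex must be male/female, got {row['sex']!r}"
                ) from None
            near_token = row["near_n8"]
            try:
                near = {"pass": NearVisionResult.PASS, "fail": NearVisionResult.FAIL,
                        NA: NearVisionResult.NA}[near_token]
            except KeyError:
                raise ParticipantFileError(
                    f"row {rownum}: near_n8 must be pass/fail/NA, "
                    f"got {near_token!r}") from None
            diag_token = row["diagnosis"]
            diagnosis = None
            if diag_token != NA:
                try:
                    diagnosis = Diagnosis(diag_token)
                except ValueError:
                    raise ParticipantFileError(
                        f"row {rownum}: unknown diagnosis {diag_token!r}") from None
            ref_token = row["reference_referral"]
            if ref_token == NA:
                referral = None
            elif ref_token in ("refer", "no_refer"):
                referral = ref_token == "refer"
            else:
                raise ParticipantFileError(
                    f"row {rownum}: reference_referral must be refer/no_refer/NA, "
                    f"got {ref_token!r}")
            try:
                records.append(ParticipantRecord(
                    id=row["id"],
                    age_years=age,
                    sex=sex,
                    child_problem_reported=_parse_tristate(
                        row["child_problem"], "child_problem", rownum),
                    pain_or_discomfort=_parse_tristate(
                        row["pain_discomfort"], "pain_discomfort", rownum),
                    vision_difficulty=_parse_tristate(
                        row["vision_difficulty"], "vision_difficulty", rownum),
                    any_eye_problem=_parse_tristate(
                        row.get("any_eye_problem", NA) or NA,
                        "any_eye_problem", rownum),
                    va_right=_parse_acuity(row["va_right"], "va_right", rownum),
                    va_left=_parse_acuity(row["va_left"], "va_left", rownum),
                    near_vision_n8_pass=near,
                    reference_diagnosis=diagnosis,
                    reference_referral=referral,
                ))
            except RecordError as e:
                raise ParticipantFileError(f"row {rownum}: {e}") from e
    return records


def write_participants(records: Sequence[ParticipantRecord],
                       path: str | Path) -> None:
    """Write records as a participant CSV; round-trips through the reader."""
    path = Path(path)
    columns = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    try:
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(columns)
            for r in records:
                writer.writerow([
                    r.id,
                    r.age_years,
                    r.sex.value,
                    r.child_problem_reported.value,
                    r.pain_or_discomfort.value,
                    r.vision_difficulty.value,
                    str(r.va_right) if r.va_right is not None else NA,
                    str(r.va_left) if r.va_left is not None else NA,
                    r.near_vision_n8_pass.value,
                    r.reference_diagnosis.value if r.reference_diagnosis else NA,
                    (NA if r.reference_referral is None
                     else ("refer" if r.reference_referral else "no_refer")),
                    r.any_eye_problem.value,
                ])
    except OSError as e:
        raise ParticipantFileError(f"cannot write participant file {path}: {e}") from e
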