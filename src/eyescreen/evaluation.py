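"""Index-vs-reference evaluation: per-iteration accuracy, counterfactual
referral strategies, and participant-flow accounting.

``evaluate_iteration`` replays one algorithm iteration over a record set and
cross-tabulates its decisions against the reference standard.  The
counterfactual strategies answer "what if we had screened differently":
vision tests only, symptom questions only, or a blanket refer-everyone-40+
rule combined with symptoms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .decision import decide, get_version
from .records import (
    NEAR_VISION_AGE,
    NearVisionResult,
    ParticipantRecord,
    TriState,
)
from .acuity import worse_than
from .decision import DEFAULT_VA_THRESHOLD
from .stats import AccuracySummary, ConfusionTable, accuracy_summary, build_confusion

__all__ = [
    "Strategy",
    "StrategySpec",
    "FlowAccounting",
    "IterationResult",
    "evaluate_iteration",
    "compare_strategies",
    "flow",
    "strategy_decision",
]


class Strategy(str, enum.Enum):
    """Counterfactual referral strategies."""

    FULL_ALGORITHM = "full_algorithm"
    VA_ONLY = "va_only"
    SYMPTOMS_ONLY = "symptoms_only"
    AGE40_OR_SYMPTOMS = "age40_or_symptoms"


@dataclass(frozen=True)
class StrategySpec:
    """A strategy name plus its parameters (iteration for full_algorithm)."""

    name: Strategy
    iteration: int = 7

    def label(self) -> str:
        if self.name is Strategy.FULL_ALGORITHM:
            return f"full_algorithm(iteration {self.iteration})"
        return self.name.value


@dataclass(frozen=True)
class FlowAccounting:
    """STARD-style participant flow: eligible minus incomplete = analyzed."""

    eligible: int
    excluded_incomplete: int

    @property
    def analyzed(self) -> int:
        return self.eligible - self.excluded_incomplete


@dataclass(frozen=True)
class IterationResult:
    iteration: int
    table: ConfusionTable
    summary: AccuracySummary
    flow: FlowAccounting


def _child_rule(r: ParticipantRecord) -> bool:
    return r.child_problem_reported is TriState.YES


def _va_trigger(r: ParticipantRecord) -> bool:
    low_va = any(va is not None and worse_than(va, DEFAULT_VA_THRESHOLD)
                 for va in (r.va_right, r.va_left))
    near_fail = (r.age_years >= NEAR_VISION_AGE
                 and r.near_vision_n8_pass is NearVisionResult.FAIL)
    return low_va or near_fail


def _symptom_trigger(r: ParticipantRecord) -> bool:
    return (r.pain_or_discomfort is TriState.YES
            or r.vision_difficulty is TriState.YES)


def strategy_decision(record: ParticipantRecord, spec: StrategySpec) -> bool:
    """Referral decision of one counterfactual strategy on one record.

    Children under 6 are decided by the guardian's report under every
    strategy (the objective/symptom split does not apply to them).
    """
    if spec.name is Strategy.FULL_ALGORITHM:
        return decide(record, get_version(spec.iteration)).refer
    if record.is_child:
        return _child_rule(record)
    if spec.name is Strategy.VA_ONLY:
        return _va_trigger(record)
    if spec.name is Strategy.SYMPTOMS_ONLY:
        return _symptom_trigger(record)
    if spec.name is Strategy.AGE40_OR_SYMPTOMS:
        return record.age_years >= NEAR_VISION_AGE or _symptom_trigger(record)
    raise ValueError(f"unknown strategy {spec.name!r}")


def _split_complete(records: Iterable[ParticipantRecord]
                    ) -> tuple[list[ParticipantRecord], int]:
    complete, excluded = [], 0
    for r in records:
        if r.reference_referral is None:
            excluded += 1
        else:
            complete.append(r)
    return complete, excluded


def evaluate_iteration(records: Sequence[ParticipantRecord], iteration: int,
                       level: float = 0.95) -> IterationResult:
    """Replay one algorithm iteration against the reference standard.

    Records without a reference referral decision are excluded and counted
    in the flow accounting, never silently dropped.
    """
    complete, excluded = _split_complete(records)
    version = get_version(iteration)
    index = [decide(r, version).refer for r in complete]
    reference = [r.reference_referral for r in complete]
    table = build_confusion(index, reference)
    return IterationResult(
        iteration=iteration,
        table=table,
        summary=accuracy_summary(table, level),
        flow=FlowAccounting(len(records), excluded),
    )


def compare_strategies(records: Sequence[ParticipantRecord],
                       strategies: Sequence[StrategySpec],
                       level: float = 0.95
                       ) -> dict[str, tuple[ConfusionTable, AccuracySummary]]:
    """Accuracy of each counterfactual strategy on the same record set.

    Returns one (confusion table, summary) row per strategy, keyed by the
    strategy label.  The reference margin (tp+fn) is identical across rows.
    """
    complete, _ = _split_complete(records)
    reference = [r.reference_referral for r in complete]
    out: dict[str, tuple[ConfusionTable, AccuracySummary]] = {}
    for spec in strategies:
        index = [strategy_decision(r, spec) for r in complete]
        table = build_confusion(index, reference)
        out[spec.label()] = (table, accuracy_summary(table, level))
    return out


def flow(records_raw: Sequence[ParticipantRecord],
         is_complete: Callable[[ParticipantRecord], bool] | None = None
         ) -> FlowAccounting:
    """Participant-flow accounting over a raw record set.

    By default a record is complete when it has a reference referral
    decision; pass ``is_complete`` to add index-side completeness checks.
    """
    if is_complete is None:
        is_complete = lambda r: r.reference_referral is not None  # noqa: E731
    excluded = sum(0 if is_complete(r) else 1 for r in records_raw)
    return FlowAccounting(len(records_raw), excluded)
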