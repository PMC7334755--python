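"""Human-readable and machine-readable accuracy reports.

Mirrors the validation report layout: one row per iteration with the 2x2
counts and sensitivity/specificity/PPV/NPV, each with its exact 95% CI,
percentages at one decimal place.
"""

from __future__ import annotations

import json
from typing import Mapping

from .stats import AccuracySummary, ConfusionTable, ProportionEstimate, accuracy_summary

__all__ = ["accuracy_rows", "format_accuracy_table", "accuracy_report_json"]

_METRICS = ("sensitivity", "specificity", "ppv", "npv")


def _estimate_fields(est: ProportionEstimate | None) -> dict:
    if est is None:
        return {"defined": False}
    return {
        "defined": True,
        "numerator": est.numerator,
        "denominator": est.denominator,
        "percent": est.percent,
        "ci_low_percent": round(100 * est.ci_low, 1),
        "ci_high_percent": round(100 * est.ci_high, 1),
        "level": est.level,
    }


def accuracy_rows(tables: Mapping[int | str, ConfusionTable],
                  level: float = 0.95) -> list[dict]:
    """One structured row per labelled confusion table."""
    rows = []
    for label, t in tables.items():
        summary = accuracy_summary(t, level)
        row = {"label": label, "tp": t.tp, "fn": t.fn, "fp": t.fp, "tn": t.tn,
               "total": t.total}
        for m in _METRICS:
            row[m] = _estimate_fields(getattr(summary, m))
        rows.append(row)
    return rows


def _fmt(summary: AccuracySummary, metric: str) -> str:
    est = getattr(summary, metric)
    return str(est) if est is not None else "undefined"


def format_accuracy_table(tables: Mapping[int | str, ConfusionTable],
                          level: float = 0.95) -> str:
    """A plain-text accuracy table, one row per iteration/strategy."""
    header = (f"{'label':>12} {'tp':>5} {'fn':>5} {'fp':>5} {'tn':>5} "
              f"{'sensitivity':>22} {'specificity':>22} {'ppv':>22} {'npv':>22}")
    lines = [header, "-" * len(header)]
    for label, t in tables.items():
        s = accuracy_summary(t, level)
        lines.append(
            f"{str(label):>12} {t.tp:>5} {t.fn:>5} {t.fp:>5} {t.tn:>5} "
            f"{_fmt(s, 'sensitivity'):>22} {_fmt(s, 'specificity'):>22} "
            f"{_fmt(s, 'ppv'):>22} {_fmt(s, 'npv'):>22}"
        )
    return "\n".join(lines)


def accuracy_report_json(tables: Mapping[int | str, ConfusionTable],
                         level: float = 0.95) -> str:
    """The same report as a JSON document."""
    return json.dumps({"level": level, "rows": accuracy_rows(tables, level)},
                      indent=2)
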