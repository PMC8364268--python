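"""Alert-system evaluation: confusion counts, sensitivity/FPR, ROC scans.

The unit of classification is the *plan* (re-plans count separately). A
positive plan is one where a re-CT decision was (or should have been)
made, with ``rect_fraction`` the treatment fraction of that decision; a
negative plan needed no action. Against an alert record:

* TP — alert triggered within ±``window`` fractions of ``rect_fraction``;
* FN — positive plan with no alert in that window (an early or late
  alert outside the window is still a miss, read literally);
* FP — any alert, at any time, on a negative plan;
* TN — negative plan with no alert.

Sensitivity = TP/(TP+FN); false positive rate = FP/(FP+TN). ROC curves
are produced by re-running the alert trigger over a grid of thresholds
and failed-histogram percentiles x, using per-entry stored failed gamma
values so no gamma map is ever recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PreconditionError
from .mqp_tracker import (
    AlertConfig,
    AlertEvent,
    MqpSeries,
    alert_events,
    detect_alert,
    series_at_percentile,
)

__all__ = [
    "CaseRecord",
    "ConfusionSummary",
    "RocCurve",
    "classify_case",
    "summarize",
    "roc_scan",
    "default_threshold_grid",
    "timing_audit",
    "read_annotations",
    "write_annotations",
    "round_display",
]

POSITIVE_SUBTYPES = ("actual_rect", "retrospective_miss", "too_late")


def round_display(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for reported metrics (0.765 -> 0.77)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CaseRecord:
    """Clinical ground truth for one plan."""

    plan_id: str
    label: str  # "positive" | "negative"
    rect_fraction: int | None = None
    positive_subtype: str | None = None
    rt_review_fraction: int | None = None

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise PreconditionError(f"plan {self.plan_id}: label must be positive|negative")
        if self.label == "positive" and self.rect_fraction is None:
            raise PreconditionError(f"plan {self.plan_id}: positive case requires rect_fraction")
        if self.label == "negative" and self.rect_fraction is not None:
            raise PreconditionError(f"plan {self.plan_id}: negative case must not carry rect_fraction")
        if self.positive_subtype is not None and self.positive_subtype not in POSITIVE_SUBTYPES:
            raise PreconditionError(
                f"plan {self.plan_id}: unknown positive_subtype {self.positive_subtype!r}"
            )


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n_plans(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise PreconditionError("sensitivity undefined: no positive cases")
        return self.tp / (self.tp + self.fn)

    @property
    def false_positive_rate(self) -> float:
        if self.fp + self.tn == 0:
            raise PreconditionError("false positive rate undefined: no negative cases")
        return self.fp / (self.fp + self.tn)

    def display(self) -> str:
        sens = round_display(self.sensitivity) if self.tp + self.fn else float("nan")
        fpr = round_display(self.false_positive_rate) if self.fp + self.tn else float("nan")
        return (
            f"plans={self.n_plans} TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn} "
            f"sensitivity={sens:.2f} false_positive_rate={fpr:.2f}"
        )


def classify_case(
    alert: AlertEvent | Sequence[AlertEvent] | None,
    case: CaseRecord,
    window_fractions: int = 3,
) -> str:
    """Classify one plan as TP/TN/FP/FN given its alert event(s).

    ``alert`` may be a single event, the full event list (initial trigger
    plus follow-ups), or None. A positive plan is TP when *any* alert
    event lands inside the window — alerts keep arriving while the
    anatomy stays changed, so an initial trigger before the window does
    not forfeit a later in-window alert; with no event in the window it
    is a miss. Suppression flags are ignored here (suppression mutes
    delivery, not the record). Window arithmetic runs on treatment
    fraction numbers, inclusive at both ends.
    """
    if alert is None:
        events: list[AlertEvent] = []
    elif isinstance(alert, AlertEvent):
        events = [alert]
    else:
        events = list(alert)
    if case.label == "positive":
        assert case.rect_fraction is not None  # enforced by CaseRecord
        for ev in events:
            if abs(ev.trigger_fraction - case.rect_fraction) <= window_fractions:
                return "TP"
        return "FN"
    return "FP" if events else "TN"


def summarize(classifications: Iterable[str]) -> ConfusionSummary:
    """Tally TP/TN/FP/FN labels into a :class:`ConfusionSummary`."""
    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    n = 0
    for label in classifications:
        if label not in counts:
            raise PreconditionError(f"unknown classification {label!r}")
        counts[label] += 1
        n += 1
    if n == 0:
        raise PreconditionError("no classifications to summarize")
    return ConfusionSummary(tp=counts["TP"], tn=counts["TN"], fp=counts["FP"], fn=counts["FN"])


@dataclass
class RocCurve:
    """ROC points over a (threshold, x) parameter grid."""

    frame: pd.DataFrame  # columns: threshold, x, tp, tn, fp, fn, sensitivity, fpr

    def points(self, x: float) -> pd.DataFrame:
        return self.frame[self.frame["x"] == x].sort_values("threshold")

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def default_threshold_grid(series: Iterable[MqpSeries]) -> np.ndarray:
    """-0.30..0 in 0.01 steps, plus every observed MQP value.

    Including the observed values guarantees no vertex of the (step
    function) ROC curve is skipped.
    """
    grid = set(np.round(np.arange(-0.30, 0.0 + 1e-9, 0.01), 10))
    for s in series:
        grid.update(float(v) for v in s.mqp_values)
    return np.array(sorted(grid))


def roc_scan(
    series_by_plan: Mapping[tuple[str, float], MqpSeries],
    cases: Sequence[CaseRecord],
    thresholds: Sequence[float] | None = None,
    xs: Sequence[float] = (80.0,),
    window_fractions: int = 3,
    consecutive_required: int = 3,
) -> RocCurve:
    """Scan alert thresholds (and percentiles x) into an ROC curve.

    ``series_by_plan`` maps ``(plan_id, x)`` to the plan's MQP series at
    that percentile; build it once per x with
    :func:`cbctalert.mqp_tracker.series_at_percentile` — no gamma
    recomputation is needed. Sensitivity (resp. FPR) is NaN when the
    cohort has no positives (resp. negatives).
    """
    for case in cases:
        for x in xs:
            if (case.plan_id, x) not in series_by_plan:
                raise PreconditionError(f"missing MQP series for plan {case.plan_id} at x={x:g}")
    if thresholds is None:
        thresholds = default_threshold_grid(
            series_by_plan[(c.plan_id, x)] for c in cases for x in xs
        )
    rows = []
    for x in xs:
        for thr in thresholds:
            config = AlertConfig(threshold=float(thr), consecutive_required=consecutive_required)
            labels = []
            for case in cases:
                events = alert_events(series_by_plan[(case.plan_id, x)], config)
                labels.append(classify_case(events, case, window_fractions))
            summary = summarize(labels)
            sens = summary.sensitivity if summary.tp + summary.fn else float("nan")
            fpr = summary.false_positive_rate if summary.fp + summary.tn else float("nan")
            rows.append(
                {
                    "threshold": float(thr),
                    "x": float(x),
                    "tp": summary.tp,
                    "tn": summary.tn,
                    "fp": summary.fp,
                    "fn": summary.fn,
                    "sensitivity": sens,
                    "fpr": fpr,
                }
            )
    return RocCurve(pd.DataFrame(rows))


def timing_audit(
    alerts: Mapping[str, AlertEvent | Sequence[AlertEvent] | None],
    cases: Sequence[CaseRecord],
    window_fractions: int = 3,
) -> dict[str, int]:
    """Four-quadrant timing comparison of the alert system vs staff review.

    For positive cases, each channel scores "+" if it acted within
    ±window fractions of the re-CT fraction; for negative cases, "+"
    means it acted at any time. Counts are keyed ``alert{+,-}_rt{+,-}``,
    split by case label. Cases without an ``rt_review_fraction``
    annotation count as no staff request.
    """
    counts = {
        f"{lbl}_alert{a}_rt{r}": 0 for lbl in ("positive", "negative") for a in "+-" for r in "+-"
    }
    for case in cases:
        alert = alerts.get(case.plan_id)
        if case.label == "positive":
            a = "+" if classify_case(alert, case, window_fractions) == "TP" else "-"
            r = "+" if case.rt_review_fraction is not None and abs(case.rt_review_fraction - case.rect_fraction) <= window_fractions else "-"
        else:
            a = "+" if classify_case(alert, case, window_fractions) == "FP" else "-"
            r = "+" if case.rt_review_fraction is not None else "-"
        counts[f"{case.label}_alert{a}_rt{r}"] += 1
    return counts


# ---------------------------------------------------------------------------
# Annotations I/O (tab-separated, '#' comments)
# ---------------------------------------------------------------------------

_COLUMNS = ["plan_id", "label", "rect_fraction", "positive_subtype", "rt_review_fraction"]


def write_annotations(cases: Sequence[CaseRecord], path: str | Path, header_note: str | None = None) -> None:
    lines = []
    if header_note:
        lines += [f"# {line}" for line in header_note.splitlines()]
    lines.append("\t".join(_COLUMNS))
    for c in cases:
        lines.append(
            "\t".join(
                [
                    c.plan_id,
                    c.label,
                    "" if c.rect_fraction is None else str(c.rect_fraction),
                    c.positive_subtype or "",
                    "" if c.rt_review_fraction is None else str(c.rt_review_fraction),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> list[CaseRecord]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotations file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"plan_id": str})
    except Exception as exc:
        raise FormatError(f"{path}: unreadable annotations ({exc})") from exc
    missing = {"plan_id", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no cases listed")
    cases = []
    for _, row in df.iterrows():
        def _opt_int(col: str) -> int | None:
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)

        subtype = row.get("positive_subtype")
        if isinstance(subtype, float) and np.isnan(subtype):
            subtype = None
        try:
            cases.append(
                CaseRecord(
                    plan_id=str(row["plan_id"]),
                    label=str(row["label"]),
                    rect_fraction=_opt_int("rect_fraction"),
                    positive_subtype=subtype or None,
                    rt_review_fraction=_opt_int("rt_review_fraction"),
                )
            )
        except PreconditionError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return cases
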