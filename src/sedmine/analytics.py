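"""Behaviour analytics over epoch timelines.

Hourly minute counts, per-day / whole-period context totals, short-break
detection and two-period comparison. All quantities are exact epoch counts;
hours are epoch-count / 60 with no rounding.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnnotationError, SedmineError
from .types import ACTIVE, STILL, EpochTimeline, MICRO_LABELS

CONTEXTS = (ACTIVE, STILL) + MICRO_LABELS  # active, still, tv, pc, unknown

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class BreakConfig:
    """A short break is a 1..max_break_min run of active epochs flanked on
    both sides by at least min_flank_still_min still epochs."""

    max_break_min: int = 5
    min_flank_still_min: int = 10

    def __post_init__(self) -> None:
        if self.max_break_min < 1 or self.min_flank_still_min < 1:
            raise SedmineError("break thresholds must be >= 1 minute")


@dataclass(frozen=True)
class ShortBreak:
    start_min: int  # absolute minute index (minute_start_s // 60)
    length_min: int


@dataclass
class BehaviourSummary:
    n_epochs: int
    hourly: dict  # hour index -> {"still": n, "active": n}
    daily_hours: dict  # day index -> {context: hours}
    context_hours: dict  # context -> hours over the whole period
    period_percentages: dict  # context -> % of epochs
    short_breaks: list = field(default_factory=list)

    @property
    def short_break_count(self) -> int:
        return len(self.short_breaks)

    @property
    def short_break_minutes(self) -> int:
        return sum(b.length_min for b in self.short_breaks)

    def to_dict(self) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "hourly": {str(h): dict(v) for h, v in sorted(self.hourly.items())},
            "daily_hours": {str(d): dict(v) for d, v in sorted(self.daily_hours.items())},
            "context_hours": dict(self.context_hours),
            "period_percentages": dict(self.period_percentages),
            "short_breaks": [
                {"start_min": b.start_min, "length_min": b.length_min}
                for b in self.short_breaks
            ],
            "short_break_count": self.short_break_count,
            "short_break_minutes": self.short_break_minutes,
        }


def _require_nonempty(tl: EpochTimeline) -> None:
    if len(tl) == 0:
        raise SedmineError("timeline is empty")


def hourly_summary(tl: EpochTimeline) -> dict:
    """Minutes per motion context for each clock hour covered.

    Hours with no epochs are absent (not zero-filled).
    """
    _require_nonempty(tl)
    out: dict[int, dict[str, int]] = {}
    for rec in tl:
        hour = int(rec.minute_start_s // SECONDS_PER_HOUR)
        bucket = out.setdefault(hour, {STILL: 0, ACTIVE: 0})
        bucket[rec.motion] += 1
    return out


def _runs(labels: list[str]) -> list[tuple[str, int, int]]:
    """Run-length encode: (label, start index, length)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return runs


def detect_short_breaks(tl: EpochTimeline, cfg: BreakConfig | None = None) -> list[ShortBreak]:
    """Maximal active runs of 1..max_break_min epochs with long still flanks."""
    _require_nonempty(tl)
    if cfg is None:
        cfg = BreakConfig()
    runs = _runs(tl.motion_labels())
    breaks = []
    for j, (label, start, length) in enumerate(runs):
        if label != ACTIVE or not (1 <= length <= cfg.max_break_min):
            continue
        if j == 0 or j == len(runs) - 1:
            continue  # no flank on one side
        prev_label, _, prev_len = runs[j - 1]
        next_label, _, next_len = runs[j + 1]
        if (
            prev_label == STILL
            and next_label == STILL
            and prev_len >= cfg.min_flank_still_min
            and next_len >= cfg.min_flank_still_min
        ):
            abs_start = int(tl[start].minute_start_s // 60)
            breaks.append(ShortBreak(start_min=abs_start, length_min=length))
    return breaks


def period_summary(tl: EpochTimeline) -> tuple[dict, dict, dict]:
    """(daily_hours, context_hours, period_percentages).

    Micro-context hours partition the still hours; percentages are over
    epochs, so active + still = 100 and tv + pc + unknown = still.
    """
    _require_nonempty(tl)
    daily_counts: dict[int, dict[str, int]] = {}
    totals = {c: 0 for c in CONTEXTS}
    for rec in tl:
        day = int(rec.minute_start_s // SECONDS_PER_DAY)
        bucket = daily_counts.setdefault(day, {c: 0 for c in CONTEXTS})
        bucket[rec.motion] += 1
        totals[rec.motion] += 1
        if rec.motion == STILL:
            bucket[rec.micro] += 1
            totals[rec.micro] += 1
    daily_hours = {
        day: {c: n / 60.0 for c, n in bucket.items()} for day, bucket in daily_counts.items()
    }
    context_hours = {c: n / 60.0 for c, n in totals.items()}
    n = len(tl)
    percentages = {c: 100.0 * totals[c] / n for c in CONTEXTS}
    return daily_hours, context_hours, percentages


def summarise(tl: EpochTimeline, break_cfg: BreakConfig | None = None) -> BehaviourSummary:
    """Full behaviour summary for one period."""
    daily_hours, context_hours, percentages = period_summary(tl)
    return BehaviourSummary(
        n_epochs=len(tl),
        hourly=hourly_summary(tl),
        daily_hours=daily_hours,
        context_hours=context_hours,
        period_percentages=percentages,
        short_breaks=detect_short_breaks(tl, break_cfg),
    )


def compare_periods(a: BehaviourSummary, b: BehaviourSummary) -> dict:
    """Per-context absolute deltas and relative % change between two
    equal-length periods, plus short-break count/minute deltas.

    Relative change is None (flagged undefined) when the baseline is zero.
    """
    if a.n_epochs != b.n_epochs:
        raise AnnotationError(
            f"periods differ in length: {a.n_epochs} vs {b.n_epochs} epochs"
        )

    def delta(x: float, y: float) -> dict:
        return {
            "absolute": y - x,
            "relative_pct": (100.0 * (y - x) / x) if x > 0 else None,
        }

    out = {
        c: delta(a.context_hours.get(c, 0.0), b.context_hours.get(c, 0.0))
        for c in CONTEXTS
    }
    out["short_break_count"] = delta(a.short_break_count, b.short_break_count)
    out["short_break_minutes"] = delta(a.short_break_minutes, b.short_break_minutes)
    return out
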