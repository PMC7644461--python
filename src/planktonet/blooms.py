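"""Bloom / non-bloom segmentation of a daily fluorescence record.

A bloom (1) starts on the first day of a run of at least two consecutive
days of positive net growth such that the growth rates summed over at least
five consecutive days starting there are positive, and (2) ends on the day
before the first subsequent run of five consecutive days of negative growth
(or at the end of the record if no such run occurs).  Net growth is the
daily log-ratio ``r_t = ln(F_t / F_{t-1})``, the standard phytoplankton net
growth estimator, which makes "sum of rates over a window positive"
equivalent to "net increase over the window".  Consecutive blooms separated
by at most two weeks of negative growth are pooled into one analysis period.

A zero rate counts as non-positive for the start rule and non-negative for
the end rule (strict reading of "positive" / "negative").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Period:
    """A labelled, inclusive date interval."""

    label: str  # "bloom" | "non_bloom"
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.label not in ("bloom", "non_bloom"):
            raise ValueError(f"unknown period label {self.label!r}")
        if self.end < self.start:
            raise ValueError("period end precedes start")

    def contains(self, date: pd.Timestamp) -> bool:
        return self.start <= date <= self.end


@dataclass
class PeriodSet:
    """Ordered, non-overlapping periods covering a campaign span."""

    periods: list[Period]
    provenance: str = ""

    def __post_init__(self) -> None:
        for a, b in zip(self.periods, self.periods[1:]):
            if b.start <= a.end:
                raise ValueError("periods overlap or are unordered")

    def with_label(self, label: str) -> list[Period]:
        return [p for p in self.periods if p.label == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.label, p.start, p.end) for p in self.periods],
            columns=["label", "start", "end"],
        )


def growth_rates(f: pd.Series) -> pd.Series:
    """Daily net growth rates ``r_t = ln(F_t / F_{t-1})``.

    The result is indexed by the second through last dates of the input.
    """
    if len(f) < 2:
        raise ValueError("need at least 2 days of fluorescence")
    bad = f[f <= 0]
    if len(bad):
        raise ValueError(f"nonpositive fluorescence on {bad.index[0].date()}")
    values = np.log(f.to_numpy(dtype=float))
    return pd.Series(np.diff(values), index=f.index[1:], name="growth_rate")


def _first_run(mask: np.ndarray, length: int, start: int = 0) -> int | None:
    """Index of the first run of ``length`` consecutive True values at or after ``start``."""
    run = 0
    for i in range(start, len(mask)):
        run = run + 1 if mask[i] else 0
        if run >= length:
            return i - length + 1
    return None


def detect_blooms(
    g: pd.Series,
    min_pos_start: int = 2,
    min_window: int = 5,
    end_neg_run: int = 5,
) -> PeriodSet:
    """Segment a growth-rate series into bloom and non-bloom periods.

    ``g`` is a daily growth-rate series as returned by :func:`growth_rates`
    (each rate indexed by the day it describes growth into).  The returned
    periods partition the full span of ``g``'s index; a record with no
    qualifying bloom yields a single non-bloom period.
    """
    if len(g) < min_window:
        raise ValueError(f"growth-rate series shorter than min_window={min_window}")
    rates = g.to_numpy(dtype=float)
    dates = g.index
    n = len(rates)
    pos = rates > 0
    neg = rates < 0
    cumsum = np.concatenate([[0.0], np.cumsum(rates)])

    events: list[str] = []
    blooms: list[tuple[int, int]] = []  # rate-index intervals, inclusive
    i = 0
    while i < n:
        if not pos[i]:
            i += 1
            continue
        # i is the first day of a positive run (either i == 0 or rates[i-1] <= 0
        # or the previous bloom ended before i).
        run_len = 1
        while i + run_len < n and pos[i + run_len]:
            run_len += 1
        started = False
        if run_len >= min_pos_start:
            # rule (2): some window of >= min_window days anchored at i has
            # positive rate sum
            for end in range(i + min_window, n + 1):
                if cumsum[end] - cumsum[i] > 0:
                    started = True
                    break
        if not started:
            i += run_len
            continue
        neg_start = _first_run(neg, end_neg_run, start=i + min_pos_start)
        if neg_start is None:
            blooms.append((i, n - 1))
            events.append(
                f"bloom starting {dates[i].date()} truncated at series end "
                f"(no {end_neg_run}-day negative run observed)"
            )
            break
        blooms.append((i, neg_start - 1))
        events.append(
            f"bloom {dates[i].date()}..{dates[neg_start - 1].date()} ended by "
            f"{end_neg_run}-day negative run starting {dates[neg_start].date()}"
        )
        i = neg_start + end_neg_run

    periods: list[Period] = []
    cursor = 0
    for s, e in blooms:
        if s > cursor:
            periods.append(Period("non_bloom", dates[cursor], dates[s - 1]))
        periods.append(Period("bloom", dates[s], dates[e]))
        cursor = e + 1
    if cursor < n:
        periods.append(Period("non_bloom", dates[cursor], dates[n - 1]))
    if not periods:
        periods = [Period("non_bloom", dates[0], dates[n - 1])]
    return PeriodSet(periods, provenance="; ".join(events) or "no bloom detected")


def pool_blooms(p: PeriodSet, max_gap_weeks: int = 2) -> PeriodSet:
    """Merge consecutive blooms separated by at most ``max_gap_weeks`` weeks.

    A non-bloom gap of ``7 * max_gap_weeks`` days or fewer between two blooms
    is absorbed into a single pooled bloom analysis period.
    """
    max_gap_days = 7 * max_gap_weeks
    blooms = [q for q in p.periods if q.label == "bloom"]
    if not blooms:
        return PeriodSet(list(p.periods), provenance=p.provenance)
    pooled: list[Period] = [blooms[0]]
    events: list[str] = []
    for b in blooms[1:]:
        gap_days = (b.start - pooled[-1].end).days - 1
        if gap_days <= max_gap_days:
            events.append(
                f"pooled bloom {pooled[-1].start.date()}..{pooled[-1].end.date()} with "
                f"{b.start.date()}..{b.end.date()} (gap {gap_days} d)"
            )
            pooled[-1] = Period("bloom", pooled[-1].start, b.end)
        else:
            pooled.append(b)
    # stitch non-bloom periods around the pooled blooms over the original span
    result: list[Period] = []
    span_start = p.periods[0].start
    span_end = p.periods[-1].end
    cursor = span_start
    for b in pooled:
        if b.start > cursor:
            result.append(Period("non_bloom", cursor, b.start - pd.Timedelta(days=1)))
        result.append(b)
        cursor = b.end + pd.Timedelta(days=1)
    if cursor <= span_end:
        result.append(Period("non_bloom", cursor, span_end))
    provenance = p.provenance
    if events:
        provenance = "; ".join([p.provenance] + events) if p.provenance else "; ".join(events)
    return PeriodSet(result, provenance=provenance)


def slice_abundance(m: pd.DataFrame, p: PeriodSet, label: str) -> pd.DataFrame:
    """Restrict an abundance matrix to sampling dates inside ``label`` periods."""
    keep = [
        d for d in m.index if any(per.contains(d) for per in p.with_label(label))
    ]
    if not keep:
        raise ValueError(f"no samples in period label {label!r}")
    return m.loc[keep]
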