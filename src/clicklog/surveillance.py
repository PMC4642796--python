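"""Daily surveillance series and drug-safety-alert uptake detection.

Term-matched search counts and media-article counts are aggregated into
gap-free daily series, smoothed with a trailing 7-day moving average, and
compared against a baseline: a signal is a run of days above
``baseline mean + k · SD``.  For a regulatory alert, the clinician-log signal
is compared with the general-media signal (onset lag, persistence), and a
pre/post report quantifies vocabulary broadening, long-click proportions,
mean dwell, and the co-occurrence of drug terms with alert-specific terms.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .engagement import ClickBoundary, DwellRecord, Label, compute_dwells, label_dwells
from .lexicon import Lexicon, QueryAnnotator, TermSet, match_events, normalize
from .log_io import Action, LogEvent, group_sessions


@dataclass
class DailySeries:
    """A date-indexed series of daily values with no gaps.

    ``values[i]`` belongs to ``start + i days``; NaN marks undefined entries
    (e.g. the warm-up of a trailing moving average).
    """

    start: date
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError("a daily series needs at least one day")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def end(self) -> date:
        return self.start + timedelta(days=len(self) - 1)

    def dates(self) -> list[date]:
        return [self.start + timedelta(days=i) for i in range(len(self))]

    def date_of(self, index: int) -> date:
        return self.start + timedelta(days=int(index))

    def index_of(self, d: date) -> int:
        i = (d - self.start).days
        if not 0 <= i < len(self):
            raise ValueError(f"{d} outside series span {self.start}..{self.end}")
        return i

    def value_on(self, d: date) -> float:
        return float(self.values[self.index_of(d)])

    def to_dict(self) -> dict[str, float]:
        return {d.isoformat(): float(v) for d, v in zip(self.dates(), self.values)}


@dataclass(frozen=True)
class MediaDoc:
    """One dated media document (news article, wire item, or blog post)."""

    title: str
    timestamp: datetime
    url: str
    content: str

    def __post_init__(self):
        if not (self.title + self.content):
            raise ValueError("media document must have a title or content")


def read_media(path: Union[str, Path]) -> list[MediaDoc]:
    """Read a JSON-lines media stream (fields title, timestamp, url, content).
    ``#``-prefixed lines are comments."""
    docs: list[MediaDoc] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            obj = json.loads(line)
            docs.append(
                MediaDoc(
                    title=obj["title"],
                    timestamp=datetime.fromisoformat(obj["timestamp"]),
                    url=obj.get("url", ""),
                    content=obj.get("content", ""),
                )
            )
    return docs


def write_media(
    docs: Iterable[MediaDoc], path: Union[str, Path], header_comment: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for d in docs:
            fh.write(
                json.dumps(
                    {
                        "title": d.title,
                        "timestamp": d.timestamp.isoformat(),
                        "url": d.url,
                        "content": d.content,
                    }
                )
                + "\n"
            )


def _day_counts(dates: Iterable[date], start: date, end: date) -> np.ndarray:
    n = (end - start).days + 1
    values = np.zeros(n)
    for d in dates:
        values[(d - start).days] += 1
    return values


def daily_query_counts(
    events: Sequence[LogEvent],
    term_set: TermSet,
    lexicon: Lexicon,
) -> tuple[DailySeries, DailySeries]:
    """(matched, total) daily search-count series, aligned and zero-filled
    over the span of all events."""
    searches = [e for e in events if e.action is Action.SEARCH]
    if not searches:
        raise ValueError("log contains no search events")
    start = min(e.timestamp for e in events).date()
    end = max(e.timestamp for e in events).date()
    matched = match_events(searches, term_set, lexicon)
    return (
        DailySeries(start, _day_counts((e.timestamp.date() for e in matched), start, end),
                    label=f"matched:{term_set.name}"),
        DailySeries(start, _day_counts((e.timestamp.date() for e in searches), start, end),
                    label="total"),
    )


def _contains_any_term(normalized_text: str, terms: Iterable[str]) -> bool:
    padded = f" {normalized_text} "
    return any(f" {t} " in padded for t in terms)


def daily_media_counts(
    docs: Sequence[MediaDoc],
    term_set: TermSet,
    lexicon: Lexicon | None = None,
) -> DailySeries:
    """Daily count of documents containing at least one term of the set
    (token-boundary match on the normalized title+content; a document counts
    once however many mentions it has)."""
    if not docs:
        raise ValueError("empty media stream")
    start = min(d.timestamp for d in docs).date()
    end = max(d.timestamp for d in docs).date()
    matched_dates = [
        d.timestamp.date()
        for d in docs
        if _contains_any_term(normalize(d.title + " " + d.content), term_set.terms)
    ]
    return DailySeries(
        start, _day_counts(matched_dates, start, end), label=f"media:{term_set.name}"
    )


def fraction_series(matched: DailySeries, total: DailySeries) -> DailySeries:
    """Elementwise matched/total; days with zero total are 0 by convention."""
    if matched.start != total.start or len(matched) != len(total):
        raise ValueError("matched and total series are misaligned")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total.values > 0, matched.values / total.values, 0.0)
    return DailySeries(matched.start, values, label=f"fraction:{matched.label}")


def moving_average(series: DailySeries, window: int = 7) -> DailySeries:
    """Trailing mean over the last ``window`` days; the first ``window-1``
    entries are NaN (undefined)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series):
        raise ValueError("window longer than series")
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    out = np.full(len(series), np.nan)
    out[window - 1 :] = (csum[window:] - csum[:-window]) / window
    return DailySeries(series.start, out, label=f"ma{window}:{series.label}")


def scale_series(series: DailySeries, factor: float) -> DailySeries:
    """Elementwise multiply (e.g. x10^7 to overlay log counts on media counts)."""
    if not factor > 0:
        raise ValueError("factor must be positive")
    return DailySeries(series.start, series.values * factor, label=series.label)


@dataclass(frozen=True)
class SignalDetection:
    onset_date: date | None
    peak_date: date | None
    elevated_duration_days: int
    threshold: float
    baseline_mean: float
    baseline_sd: float
    degenerate_baseline: bool = False


def detect_signal(
    series: DailySeries,
    baseline: tuple[date, date] | None = None,
    k: float = 3.0,
    min_run: int = 3,
    exclude: tuple[date, date] | None = None,
) -> SignalDetection:
    """Detect a sustained elevation above the baseline.

    The threshold is baseline mean + ``k`` · baseline SD (sample SD); the
    onset is the first day starting ``min_run`` consecutive days strictly
    above threshold; the peak is the argmax from onset on; the elevation ends
    on the first day starting ``min_run`` consecutive days at or below
    threshold.  ``baseline`` is an inclusive date range, defaulting to the
    whole series minus an optional ``exclude`` window (so a suspected event
    window does not contaminate the baseline).  An all-constant baseline has
    zero SD; the threshold then falls back to mean + 1 and the detection is
    flagged degenerate.
    """
    v = series.values
    n = len(series)
    mask = np.ones(n, dtype=bool)
    if baseline is not None:
        mask[:] = False
        mask[series.index_of(baseline[0]) : series.index_of(baseline[1]) + 1] = True
    if exclude is not None:
        lo = max((exclude[0] - series.start).days, 0)
        hi = min((exclude[1] - series.start).days, n - 1)
        if lo <= hi:
            mask[lo : hi + 1] = False
    base = v[mask & ~np.isnan(v)]
    if base.size < 2:
        raise ValueError("baseline must contain at least 2 defined days")
    bm = float(np.mean(base))
    bs = float(np.std(base, ddof=1))
    degenerate = bs == 0.0
    threshold = bm + 1.0 if degenerate else bm + k * bs

    above = np.zeros(n, dtype=bool)
    defined = ~np.isnan(v)
    above[defined] = v[defined] > threshold

    onset_idx: int | None = None
    run = 0
    for i in range(n):
        run = run + 1 if above[i] else 0
        if run == min_run:
            onset_idx = i - min_run + 1
            break
    if onset_idx is None:
        return SignalDetection(None, None, 0, threshold, bm, bs, degenerate)

    post = np.where(defined, v, -np.inf)[onset_idx:]
    peak_idx = onset_idx + int(np.argmax(post))

    end_idx = n  # exclusive end of elevation
    run = 0
    for i in range(onset_idx, n):
        run = run + 1 if not above[i] else 0
        if run == min_run:
            end_idx = i - min_run + 1
            break
    return SignalDetection(
        onset_date=series.date_of(onset_idx),
        peak_date=series.date_of(peak_idx),
        elevated_duration_days=end_idx - onset_idx,
        threshold=threshold,
        baseline_mean=bm,
        baseline_sd=bs,
        degenerate_baseline=degenerate,
    )


@dataclass(frozen=True)
class StreamComparison:
    """Log vs media alert response: how much later and how much longer."""

    lag_days: int
    duration_ratio: float


def compare_streams(
    log_signal: SignalDetection, media_signal: SignalDetection
) -> StreamComparison:
    """Onset lag (log minus media, days) and elevated-duration ratio."""
    if log_signal.onset_date is None:
        raise ValueError("no onset detected in the log stream")
    if media_signal.onset_date is None:
        raise ValueError("no onset detected in the media stream")
    ratio = (
        log_signal.elevated_duration_days / media_signal.elevated_duration_days
        if media_signal.elevated_duration_days
        else math.inf
    )
    return StreamComparison(
        lag_days=(log_signal.onset_date - media_signal.onset_date).days,
        duration_ratio=ratio,
    )


@dataclass(frozen=True)
class TopicPrePost:
    topic_id: str
    pre_unique_terms: int
    post_unique_terms: int
    pre_long_click_proportion: float
    post_long_click_proportion: float


@dataclass(frozen=True)
class AlertReport:
    """Pre/post comparison of drug-related search behavior around an alert."""

    alert_date: date
    topics: tuple[TopicPrePost, ...]
    pre_mean_dwell_seconds: float
    post_mean_dwell_seconds: float
    pre_specificity_count: int
    post_specificity_count: int
    pre_n_matched_searches: int
    post_n_matched_searches: int
    onset_date: date | None = None
    onset_lag_days: int | None = None
    peak_date: date | None = None
    elevated_duration_days: int | None = None


def _long_prop(dwells: list[DwellRecord]) -> float:
    n_long = sum(1 for d in dwells if d.label is Label.LONG)
    n_short = sum(1 for d in dwells if d.label is Label.SHORT)
    return n_long / (n_long + n_short) if (n_long + n_short) else 0.0


def pre_post_report(
    events: Sequence[LogEvent],
    alert_date: date,
    drug_term_set: TermSet,
    specificity_terms: Iterable[str],
    lexicon: Lexicon,
    boundary: ClickBoundary,
    window_days: int | None = None,
) -> AlertReport:
    """Quantify alert uptake: behavior before vs after the alert date.

    Windows default to [log start, alert) and [alert, log end]; passing
    ``window_days`` restricts both to symmetric windows of that length around
    the alert.  Topics *reached from* searches matching the drug term set are
    selected, then, per topic and window, the number of unique initiating
    terms and the long-click proportion over all its views; plus the mean
    dwell on those topics and the count of searches containing both a drug
    term and at least one specificity term (annotation-level drug match,
    token-boundary specificity match).
    """
    spec_terms = [normalize(t) for t in specificity_terms]
    annotator = QueryAnnotator(lexicon)

    if window_days is not None:
        lo = datetime.combine(alert_date - timedelta(days=window_days), datetime.min.time())
        hi = datetime.combine(alert_date + timedelta(days=window_days), datetime.min.time())
        events = [e for e in events if lo <= e.timestamp < hi]
    alert_dt = datetime.combine(alert_date, datetime.min.time())

    searches = [e for e in events if e.action is Action.SEARCH]
    matched_searches = match_events(searches, drug_term_set, lexicon, annotator)
    pre_matched = [e for e in matched_searches if e.timestamp < alert_dt]
    post_matched = [e for e in matched_searches if e.timestamp >= alert_dt]
    if not pre_matched:
        raise ValueError("no drug-matched search events before the alert date")
    if not post_matched:
        raise ValueError("no drug-matched search events after the alert date")

    dwells = label_dwells(
        [d for s in group_sessions(events) for d in compute_dwells(s)], boundary
    )

    def initiated_by_drug(d: DwellRecord) -> bool:
        return d.initiating_term is not None and bool(
            annotator(d.initiating_term).matched_terms & drug_term_set.terms
        )

    drug_topics = sorted({d.topic_id for d in dwells if initiated_by_drug(d)})
    by_topic: dict[str, list[DwellRecord]] = defaultdict(list)
    for d in dwells:
        if d.topic_id in drug_topics:
            by_topic[d.topic_id].append(d)

    topics = []
    pre_all: list[DwellRecord] = []
    post_all: list[DwellRecord] = []
    for topic in drug_topics:
        pre = [d for d in by_topic[topic] if d.start < alert_dt]
        post = [d for d in by_topic[topic] if d.start >= alert_dt]
        pre_all += pre
        post_all += post
        topics.append(
            TopicPrePost(
                topic_id=topic,
                pre_unique_terms=len({d.initiating_term for d in pre} - {None}),
                post_unique_terms=len({d.initiating_term for d in post} - {None}),
                pre_long_click_proportion=_long_prop(pre),
                post_long_click_proportion=_long_prop(post),
            )
        )

    def specificity_count(group: list[LogEvent]) -> int:
        return sum(
            1
            for e in group
            if _contains_any_term(normalize(e.payload), spec_terms)
        )

    return AlertReport(
        alert_date=alert_date,
        topics=tuple(topics),
        pre_mean_dwell_seconds=(
            float(np.mean([d.duration for d in pre_all])) if pre_all else float("nan")
        ),
        post_mean_dwell_seconds=(
            float(np.mean([d.duration for d in post_all])) if post_all else float("nan")
        ),
        pre_specificity_count=specificity_count(pre_matched),
        post_specificity_count=specificity_count(post_matched),
        pre_n_matched_searches=len(pre_matched),
        post_n_matched_searches=len(post_matched),
    )
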