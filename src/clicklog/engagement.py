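"""Dwell-time engagement: short vs long clicks and robust thresholds.

The dwell time of a topic view is the gap between the view and the next
event that terminates it — a search, or a view of a different topic.
Consecutive views of the same topic (including subtopic clicks within the
page) merge into one dwell; a view that ends the session has no measurable
dwell and is dropped.

Views are split into *short clicks* and *long clicks* at the geometric mean
of all dwell times (the mean of the log-transformed durations converted
back to seconds; the log base cancels).  Long clicks proxy user interest.
Per-topic and per-term long-click proportions are summarized, and high/low
engagement thresholds are set with the Hampel identifier
(median ± k · 1.4826 · MAD).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from datetime import datetime
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .lexicon import normalize
from .log_io import Action, Session


class Label(str, Enum):
    SHORT = "short"
    LONG = "long"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True, slots=True)
class DwellRecord:
    """One merged topic visit with its computed duration."""

    session_id: str
    topic_id: str
    start: datetime
    duration: float  # seconds, > 0
    initiating_term: str | None  # normalized nearest preceding query, if any
    label: Label = Label.UNCLASSIFIED

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("dwell duration must be positive")


@dataclass(frozen=True)
class ClickBoundary:
    """Short/long decision boundary: geometric mean of dwell durations."""

    boundary_seconds: float
    n_durations: int

    def __post_init__(self):
        if not self.boundary_seconds > 0:
            raise ValueError("boundary must be positive")


@dataclass(frozen=True)
class TopicEngagement:
    topic_id: str
    n_views: int
    long_click_proportion: float
    n_unique_initiating_terms: int


@dataclass(frozen=True)
class TermEngagement:
    term: str
    n_views: int
    long_click_proportion: float
    n_unique_topics: int


@dataclass(frozen=True)
class HampelBounds:
    low: float
    high: float
    median: float
    scaled_mad: float
    degenerate: bool = False


@dataclass(frozen=True)
class MannWhitneyComparison:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    method: str


def compute_dwells(session: Session) -> list[DwellRecord]:
    """Dwell records for one time-ordered session.

    A dwell starts at the first view of a topic block and ends at the next
    search or different-topic view; subtopic views of the same topic extend
    the block.  The block open when the session ends is dropped (its end is
    unobserved), as are zero-length dwells (equal timestamps at seconds
    resolution).  The initiating term is the normalized payload of the most
    recent earlier search in the session, absent if none.
    """
    dwells: list[DwellRecord] = []
    current_term: str | None = None
    block_topic: str | None = None
    block_start: datetime | None = None
    block_term: str | None = None

    def close(end: datetime) -> None:
        nonlocal block_topic, block_start
        duration = (end - block_start).total_seconds()
        if duration > 0:
            dwells.append(
                DwellRecord(
                    session_id=session.session_id,
                    topic_id=block_topic,
                    start=block_start,
                    duration=duration,
                    initiating_term=block_term,
                )
            )
        block_topic = None
        block_start = None

    for event in session.events:
        if event.action is Action.SEARCH:
            if block_topic is not None:
                close(event.timestamp)
            current_term = normalize(event.payload)
        else:
            topic = event.topic_id
            if block_topic == topic:
                continue  # same-topic (sub)view extends the block
            if block_topic is not None:
                close(event.timestamp)
            block_topic = topic
            block_start = event.timestamp
            block_term = current_term
    # final open block has no terminating event: excluded
    return dwells


def fit_boundary(durations: Sequence[float]) -> ClickBoundary:
    """Geometric mean of positive dwell durations, in seconds."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("cannot fit a boundary on no durations")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return ClickBoundary(
        boundary_seconds=float(np.exp(np.mean(np.log(d)))), n_durations=int(d.size)
    )


def classify(duration: float, boundary: ClickBoundary) -> Label:
    """Long iff strictly above the boundary; ties are short."""
    return Label.LONG if duration > boundary.boundary_seconds else Label.SHORT


def label_dwells(
    dwells: Iterable[DwellRecord], boundary: ClickBoundary
) -> list[DwellRecord]:
    return [replace(d, label=classify(d.duration, boundary)) for d in dwells]


def _engagement(
    dwells: Iterable[DwellRecord], key: str, distinct: str
) -> list[tuple[str, int, float, int]]:
    groups: dict[str, list[DwellRecord]] = defaultdict(list)
    for d in dwells:
        k = getattr(d, key)
        if k is None:
            continue
        groups[k].append(d)
    out = []
    for k in sorted(groups):
        ds = groups[k]
        n_long = sum(1 for d in ds if d.label is Label.LONG)
        n_short = sum(1 for d in ds if d.label is Label.SHORT)
        n_labeled = n_long + n_short
        prop = n_long / n_labeled if n_labeled else 0.0
        uniq = {getattr(d, distinct) for d in ds} - {None}
        out.append((k, len(ds), prop, len(uniq)))
    return out


def topic_engagement(dwells: Iterable[DwellRecord]) -> list[TopicEngagement]:
    """Per-topic view counts, long-click proportion, and the number of unique
    search terms that initiated views of the topic."""
    return [
        TopicEngagement(k, n, p, u)
        for k, n, p, u in _engagement(dwells, "topic_id", "initiating_term")
    ]


def term_engagement(dwells: Iterable[DwellRecord]) -> list[TermEngagement]:
    """Per-initiating-term view counts, long-click proportion, and the number
    of distinct topics the term led to.  Dwells with no initiating search are
    not attributable and are skipped."""
    return [
        TermEngagement(k, n, p, u)
        for k, n, p, u in _engagement(dwells, "initiating_term", "topic_id")
    ]


def hampel_bounds(
    values: Sequence[float], k: float = 3.0, clamp_to_unit: bool | None = None
) -> HampelBounds:
    """Hampel identifier: median ± k · 1.4826 · MAD.

    The 1.4826 factor makes the MAD a consistent estimator of the Gaussian
    standard deviation.  When every input lies in [0, 1] (proportions) the
    bounds are clamped to [0, 1]; pass ``clamp_to_unit`` to override.  All
    identical values give zero MAD and collapsed bounds, flagged degenerate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = float(np.median(v))
    mad = float(np.median(np.abs(v - m)))
    scaled = 1.4826 * mad
    low = m - k * scaled
    high = m + k * scaled
    if clamp_to_unit is None:
        clamp_to_unit = bool(np.all((v >= 0) & (v <= 1)))
    if clamp_to_unit:
        low = max(low, 0.0)
        high = min(high, 1.0)
    return HampelBounds(
        low=low, high=high, median=m, scaled_mad=scaled, degenerate=(mad == 0)
    )


def compare_initiating_term_counts(
    high_group: Sequence[float], low_group: Sequence[float]
) -> MannWhitneyComparison:
    """Two-sided Mann-Whitney U comparison of unique-initiating-term counts.

    Exact null distribution when both groups have ≤8 tie-free observations,
    tie-corrected normal approximation otherwise.  Descriptive statistics
    (median, IQR, mean, SD per group) are returned alongside.
    """
    a = np.asarray(high_group, dtype=float)
    b = np.asarray(low_group, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size <= 8 and b.size <= 8 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)

    def iqr(x: np.ndarray) -> float:
        q75, q25 = np.percentile(x, [75, 25])
        return float(q75 - q25)

    def sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return MannWhitneyComparison(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=iqr(a),
        iqr_b=iqr(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=sd(a),
        sd_b=sd(b),
        method=method,
    )
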