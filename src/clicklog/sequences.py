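"""Mining contiguous topic-view sequences within sessions.

Within a session, maximal runs of topic views uninterrupted by a search are
extracted (subtopic views fold onto their parent topic; immediately repeated
topics collapse, since subtopic clicks within one page are not navigation).
Every contiguous window of length ``min_len``..``max_len`` inside a run is
one occurrence of that pattern, and the search immediately preceding the run
is credited as its initiating term.  Sequences longer than 4 tend to be
dominated by topic "switching" (alternating between two topics), quantified
here by :func:`switching_fraction`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import normalize
from .log_io import Action, Session


@dataclass(frozen=True)
class TopicRun:
    """A maximal uninterrupted run of distinct-adjacent topic views."""

    topics: tuple[str, ...]
    initiating_term: str | None


@dataclass
class SequencePattern:
    """An ordered run of topics with its occurrence count and the tally of
    search terms observed just prior to its occurrences."""

    topics: tuple[str, ...]
    count: int
    initiating_terms: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.topics)


def topic_runs(session: Session) -> list[TopicRun]:
    """Extract the session's topic runs.

    The event preceding a run is either a search (its payload, normalized, is
    the run's initiating term) or nothing (session starts with views).
    """
    runs: list[TopicRun] = []
    current: list[str] = []
    current_term: str | None = None
    last_search: str | None = None

    def flush() -> None:
        nonlocal current
        if current:
            runs.append(TopicRun(tuple(current), current_term))
            current = []

    for event in session.events:
        if event.action is Action.SEARCH:
            flush()
            last_search = normalize(event.payload)
        else:
            topic = event.topic_id
            if not current:
                current_term = last_search
                current.append(topic)
            elif current[-1] != topic:
                current.append(topic)
            # identical adjacent topic: collapsed
    flush()
    return runs


def mine_sequences(
    sessions: Iterable[Session], min_len: int = 2, max_len: int = 4
) -> list[SequencePattern]:
    """Count every contiguous window of length ``min_len``..``max_len`` in
    every run, crediting the run's initiating term to each window.

    The result is sorted by descending count, then lexicographically by topic
    tuple, so it is invariant to session input order.
    """
    if min_len < 2:
        raise ValueError("min_len must be at least 2")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    counts: dict[tuple[str, ...], SequencePattern] = {}
    for session in sessions:
        for run in topic_runs(session):
            n = len(run.topics)
            for length in range(min_len, max_len + 1):
                for i in range(n - length + 1):
                    window = run.topics[i : i + length]
                    pat = counts.get(window)
                    if pat is None:
                        pat = counts[window] = SequencePattern(window, 0)
                    pat.count += 1
                    if run.initiating_term is not None:
                        pat.initiating_terms[run.initiating_term] += 1
    return sorted(counts.values(), key=lambda p: (-p.count, p.topics))


def switching_fraction(topics: Sequence[str] | SequencePattern) -> float:
    """Fraction of positions i with topics[i] == topics[i+2].

    1.0 for strict two-topic alternation (A,B,A[,B,...]); 0.0 when no
    two-apart repeats exist, including all sequences shorter than 3.
    """
    if isinstance(topics, SequencePattern):
        topics = topics.topics
    if len(topics) < 2:
        raise ValueError("need a sequence of length >= 2")
    pairs = len(topics) - 2
    if pairs <= 0:
        return 0.0
    return sum(topics[i] == topics[i + 2] for i in range(pairs)) / pairs


def top_patterns(
    patterns: Iterable[SequencePattern],
    k: int,
    lengths: Sequence[int] = (3, 4),
    n_terms: int = 5,
) -> list[tuple[SequencePattern, list[tuple[str, int]]]]:
    """Top-``k`` patterns of the requested lengths by count.

    Count ties break lexicographically on the topic tuple; each pattern comes
    with its top-``n_terms`` initiating terms by count (term-name tie-break).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    wanted = [p for p in patterns if len(p) in set(lengths)]
    wanted.sort(key=lambda p: (-p.count, p.topics))
    out = []
    for p in wanted[:k]:
        terms = sorted(p.initiating_terms.items(), key=lambda kv: (-kv[1], kv[0]))
        out.append((p, terms[:n_terms]))
    return out
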