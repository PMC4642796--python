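"""Independent brute-force reference implementations used by the tests.

Everything here is written straight from the definitions (linear scans,
full enumeration), deliberately ignoring the package's own code paths.
"""

from __future__ import annotations

import itertools
from collections import Counter
from datetime import datetime, timedelta

import numpy as np

from clicklog.log_io import Action, LogEvent, Session


def parent_topic(event: LogEvent) -> str:
    if event.action is Action.SUBTOPIC_VIEW:
        return event.payload.split("/", 1)[0]
    return event.payload


def dwell_oracle(session: Session) -> list[tuple[str, float, str | None]]:
    """(topic, duration, initiating_term) triples, straight from the rules.

    Walk the event list; a view block starts at a view whose topic differs
    from the running block; it ends at the next search or different-topic
    view; blocks ending the session, and zero-length blocks, are dropped.
    Terms are compared on the raw lowercase payload (the tests feed already
    normalized payloads).
    """
    out = []
    events = session.events
    i = 0
    last_search = None
    while i < len(events):
        ev = events[i]
        if ev.action is Action.SEARCH:
            last_search = ev.payload
            i += 1
            continue
        topic = parent_topic(ev)
        start = ev.timestamp
        term = last_search
        j = i + 1
        end = None
        while j < len(events):
            nxt = events[j]
            if nxt.action is Action.SEARCH or parent_topic(nxt) != topic:
                end = nxt.timestamp
                break
            j += 1
        if end is not None:
            duration = (end - start).total_seconds()
            if duration > 0:
                out.append((topic, duration, term))
        i = j
    return out


def runs_oracle(session: Session) -> list[tuple[tuple[str, ...], str | None]]:
    """Maximal collapsed view-runs with the immediately preceding search."""
    runs = []
    events = session.events
    i = 0
    while i < len(events):
        if events[i].action is Action.SEARCH:
            i += 1
            continue
        initiator = (
            events[i - 1].payload
            if i > 0 and events[i - 1].action is Action.SEARCH
            else None
        )
        topics: list[str] = []
        while i < len(events) and events[i].action is not Action.SEARCH:
            t = parent_topic(events[i])
            if not topics or topics[-1] != t:
                topics.append(t)
            i += 1
        runs.append((tuple(topics), initiator))
    return runs


def mine_oracle(
    sessions, min_len=2, max_len=4
) -> dict[tuple[str, ...], tuple[int, Counter]]:
    """Window counts by explicit enumeration over oracle runs."""
    counts: dict[tuple[str, ...], int] = Counter()
    terms: dict[tuple[str, ...], Counter] = {}
    for session in sessions:
        for topics, initiator in runs_oracle(session):
            for length in range(min_len, max_len + 1):
                for i in range(len(topics) - length + 1):
                    w = topics[i : i + length]
                    counts[w] += 1
                    if initiator is not None:
                        terms.setdefault(w, Counter())[initiator] += 1
    return {w: (c, terms.get(w, Counter())) for w, c in counts.items()}


def moving_average_oracle(values, window):
    out = [float("nan")] * len(values)
    for i in range(window - 1, len(values)):
        out[i] = sum(values[i - window + 1 : i + 1]) / window
    return out


def hampel_oracle(values, k=3.0):
    v = sorted(values)
    n = len(v)
    m = (v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2)
    dev = sorted(abs(x - m) for x in values)
    mad = dev[n // 2] if n % 2 else (dev[n // 2 - 1] + dev[n // 2]) / 2
    return m - k * 1.4826 * mad, m + k * 1.4826 * mad


def one_hop_closure_oracle(seeds, lexicon, exclusions=frozenset()):
    """Brute-force union over seed -> concepts -> all their terms."""
    terms = set(seeds)
    for s in seeds:
        for concept, syns in lexicon.concept_terms.items():
            if s in syns:
                terms |= set(syns)
    return terms - set(exclusions)


def annotate_oracle(normalized_query: str, term_set: set[str]) -> list[str]:
    """Greedy longest-match-first over token spans, by direct span search."""
    tokens = normalized_query.split()
    max_len = max((len(t.split()) for t in term_set), default=0)
    matched = []
    i = 0
    while i < len(tokens):
        hit = None
        for span in range(min(max_len, len(tokens) - i), 0, -1):
            cand = " ".join(tokens[i : i + span])
            if cand in term_set:
                hit = (cand, span)
                break
        if hit:
            matched.append(hit[0])
            i += hit[1]
        else:
            i += 1
    return matched


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
        )

    u_obs = u_stat(a, b)
    mu = n1 * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


def random_log(rng: np.random.Generator, n_events=1000, n_sessions=50,
               n_topics=20, n_terms=30) -> list[LogEvent]:
    """A structureless random log for oracle-equivalence tests."""
    base = datetime(2011, 1, 1)
    events = []
    for _ in range(n_events):
        sid = f"s{int(rng.integers(n_sessions))}"
        ts = base + timedelta(seconds=int(rng.integers(0, 86400 * 5)))
        r = rng.random()
        if r < 0.3:
            ev = LogEvent(sid, "inst0", ts, Action.SEARCH,
                          f"term{int(rng.integers(n_terms))}")
        elif r < 0.85:
            ev = LogEvent(sid, "inst0", ts, Action.TOPIC_VIEW,
                          f"T{int(rng.integers(n_topics))}")
        else:
            ev = LogEvent(sid, "inst0", ts, Action.SUBTOPIC_VIEW,
                          f"T{int(rng.integers(n_topics))}/s{int(rng.integers(3))}")
        events.append(ev)
    return events
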