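from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from clicklog.engagement import ClickBoundary
from clicklog.lexicon import TermSet
from clicklog.log_io import Action, LogEvent
from clicklog.surveillance import (
    DailySeries,
    MediaDoc,
    compare_streams,
    daily_media_counts,
    daily_query_counts,
    detect_signal,
    fraction_series,
    moving_average,
    pre_post_report,
    read_media,
    scale_series,
    write_media,
)
from oracles import moving_average_oracle


@pytest.fixture
def flu_set():
    return TermSet(name="flu", terms=frozenset({"influenza"}))


def _search(sid, day, payload, second=0):
    return LogEvent(sid, "i1", datetime(2011, 1, day, 0, 0, second),
                    Action.SEARCH, payload)


def test_daily_query_counts_matched_and_total(tiny_lexicon, flu_set):
    events = [
        _search("s1", 1, "influenza"),
        _search("s2", 1, "influenza b"),
        _search("s3", 1, "celexa"),
        _search("s4", 3, "celexa"),
    ]
    matched, total = daily_query_counts(events, flu_set, tiny_lexicon)
    assert matched.start == total.start == date(2011, 1, 1)
    assert list(matched.values) == [2, 0, 0]  # day 2 gap-filled
    assert list(total.values) == [3, 0, 1]
    with pytest.raises(ValueError):
        daily_query_counts([], flu_set, tiny_lexicon)


def test_daily_media_counts_document_level(tiny_lexicon, flu_set):
    docs = [
        MediaDoc("flu news", datetime(2011, 1, 1, 8), "u1",
                 "influenza influenza influenza"),  # counts once
        MediaDoc("more", datetime(2011, 1, 1, 9), "u2", "Influenza season."),
        MediaDoc("other", datetime(2011, 1, 2, 9), "u3", "markets rallied"),
    ]
    series = daily_media_counts(docs, flu_set)
    assert list(series.values) == [2, 0]


def test_media_round_trip(tmp_path):
    docs = [MediaDoc("t", datetime(2011, 1, 1, 5), "u", "c")]
    p = tmp_path / "media.jsonl"
    write_media(docs, p, header_comment="seed=1")
    assert read_media(p) == docs


def test_fraction_series_convention_and_oracle():
    matched = DailySeries(date(2011, 1, 1), [3, 0, 1])
    total = DailySeries(date(2011, 1, 1), [10, 0, 4])
    f = fraction_series(matched, total)
    assert list(f.values) == pytest.approx([0.3, 0.0, 0.25])
    rng = np.random.default_rng(2)
    m = rng.integers(0, 5, size=50).astype(float)
    t = m + rng.integers(0, 10, size=50)
    f = fraction_series(DailySeries(date(2011, 1, 1), m), DailySeries(date(2011, 1, 1), t))
    for fi, mi, ti in zip(f.values, m, t):
        assert fi == (mi / ti if ti else 0.0)
    with pytest.raises(ValueError):
        fraction_series(matched, DailySeries(date(2011, 1, 2), [1, 1, 1]))


def test_moving_average_examples_and_oracle():
    s = DailySeries(date(2011, 1, 1), [1, 2, 3, 4])
    ma = moving_average(s, 3)
    assert np.isnan(ma.values[0]) and np.isnan(ma.values[1])
    assert list(ma.values[2:]) == [2.0, 3.0]
    const = moving_average(DailySeries(date(2011, 1, 1), [5.0] * 10), 7)
    assert list(const.values[6:]) == [5.0] * 4
    rng = np.random.default_rng(8)
    v = rng.random(200)
    got = moving_average(DailySeries(date(2011, 1, 1), v), 7).values
    exp = moving_average_oracle(list(v), 7)
    np.testing.assert_allclose(got[6:], exp[6:], rtol=1e-12)
    with pytest.raises(ValueError):
        moving_average(s, 5)


def test_scale_series_identity_and_argmax_preserved():
    v = np.array([1e-7, 3e-7, 2e-7])
    s = DailySeries(date(2011, 1, 1), v)
    scaled = scale_series(s, 1e7)
    assert list(scaled.values) == pytest.approx([1.0, 3.0, 2.0])
    assert np.argmax(scaled.values) == np.argmax(s.values)
    assert list(scale_series(s, 1).values) == pytest.approx(list(v))


def test_detect_signal_forced_crossing():
    rng = np.random.default_rng(4)
    v = rng.normal(10, 1, size=100)
    v[40:50] = 20.0
    s = DailySeries(date(2011, 1, 1), v)
    sig = detect_signal(s, baseline=(date(2011, 1, 1), date(2011, 2, 5)), k=3)
    assert sig.onset_date == date(2011, 1, 1) + timedelta(days=40)
    assert sig.elevated_duration_days == 10
    assert sig.peak_date is not None


def test_detect_signal_flat_series_no_onset_degenerate():
    s = DailySeries(date(2011, 1, 1), [5.0] * 30)
    sig = detect_signal(s)
    assert sig.onset_date is None
    assert sig.degenerate_baseline and sig.threshold == 6.0


def test_detect_signal_translation_equivariance():
    base = np.zeros(120)
    for shift in (0, 7, 23):
        v = base.copy()
        v[60 + shift : 70 + shift] = 50.0
        rng = np.random.default_rng(1)
        v += rng.normal(5, 0.5, size=120)
        sig = detect_signal(
            DailySeries(date(2011, 1, 1), v),
            baseline=(date(2011, 1, 1), date(2011, 2, 19)),
        )
        assert sig.onset_date == date(2011, 1, 1) + timedelta(days=60 + shift)


def test_compare_streams_lag_and_errors():
    from clicklog.surveillance import SignalDetection

    log_sig = SignalDetection(date(2011, 9, 3), date(2011, 9, 10), 60, 5, 2, 1)
    med_sig = SignalDetection(date(2011, 8, 24), date(2011, 8, 25), 6, 5, 2, 1)
    cmp = compare_streams(log_sig, med_sig)
    assert cmp.lag_days == 10
    assert cmp.duration_ratio == pytest.approx(10.0)
    same = compare_streams(log_sig, log_sig)
    assert same.lag_days == 0 and same.duration_ratio == 1.0
    none_sig = SignalDetection(None, None, 0, 5, 2, 1)
    with pytest.raises(ValueError, match="media"):
        compare_streams(log_sig, none_sig)
    with pytest.raises(ValueError, match="log"):
        compare_streams(none_sig, med_sig)


def _toy_alert_log():
    """Hand-countable pre/post log around an 2011-08-24 alert."""
    drug_searches = [
        ("s1", datetime(2011, 8, 20, 9, 0), "celexa"),
        ("s2", datetime(2011, 8, 21, 9, 0), "citalopram dose"),
        ("s3", datetime(2011, 8, 25, 9, 0), "celexa"),
        ("s4", datetime(2011, 8, 26, 9, 0), "celexa long qt"),
        ("s5", datetime(2011, 8, 27, 9, 0), "citalopram heart"),
    ]
    events = []
    for sid, t, q in drug_searches:
        events.append(LogEvent(sid, "i1", t, Action.SEARCH, q))
        events.append(LogEvent(sid, "i1", t + timedelta(seconds=5),
                               Action.TOPIC_VIEW, "t_cit"))
        events.append(LogEvent(sid, "i1", t + timedelta(seconds=205),
                               Action.SEARCH, "zzq unrelated"))
    return events


def test_pre_post_report_hand_counted(tiny_lexicon):
    drug_set = TermSet(name="celexa", terms=frozenset({"celexa", "citalopram"}))
    report = pre_post_report(
        _toy_alert_log(),
        date(2011, 8, 24),
        drug_set,
        ["long qt", "heart", "rhythm"],
        tiny_lexicon,
        ClickBoundary(143.79, 0),
    )
    (topic,) = report.topics
    assert topic.topic_id == "t_cit"
    assert topic.pre_unique_terms == 2
    assert topic.post_unique_terms == 3
    # all toy dwells are 200 s -> long clicks
    assert topic.pre_long_click_proportion == 1.0
    assert report.pre_mean_dwell_seconds == pytest.approx(200.0)
    assert report.pre_specificity_count == 0
    assert report.post_specificity_count == 2


def test_pre_post_report_requires_both_windows(tiny_lexicon):
    drug_set = TermSet(name="celexa", terms=frozenset({"celexa", "citalopram"}))
    events = _toy_alert_log()
    with pytest.raises(ValueError, match="before"):
        pre_post_report(events, date(2011, 8, 1), drug_set, ["heart"],
                        tiny_lexicon, ClickBoundary(143.79, 0))
    with pytest.raises(ValueError, match="after"):
        pre_post_report(events, date(2011, 12, 1), drug_set, ["heart"],
                        tiny_lexicon, ClickBoundary(143.79, 0))
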