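# clicklog

Mining the usage logs of an online clinical reference: what health-care
professionals search for, how long they engage with the topic pages their
searches lead to, how they navigate between topics, and how quickly and
persistently they respond to a drug-safety alert compared with the general
news media.

The package is aimed at researchers in infodemiology and pharmacovigilance
who work with sessionized clickstream data: event logs with one row per user
action (free-text search, topic view, or subtopic view), a session
identifier, an institution label, and a seconds-resolution timestamp.
Because real clinician logs are proprietary, the package ships a seeded
synthetic-data generator that emulates their statistical structure with
recorded ground truth, so the whole pipeline is exercisable and testable
end to end.

## What it computes

**Concept annotation.** Free-text queries are annotated against a lexicon
(term → concepts, concept → semantic category among diseases/symptoms,
drugs, devices, procedures, plus a concept hierarchy) by greedy
longest-match-first, token-boundary matching. Term sets for clinical
entities (body systems, condition groups, drug synonym sets) are built by
one-hop expansion — seed terms → their concepts → those concepts' full
synonym sets — with an explicit exclusion list standing in for manual
curation.

**Dwell-time engagement.** The dwell time of a topic view is the gap to the
next event that terminates it (a search or a different-topic view; subtopic
clicks extend the view, and a view that ends its session is dropped as
unmeasurable). Views are split at the geometric mean of all dwell times,

> boundary = exp( mean( ln d_i ) ),

into *short clicks* (d ≤ boundary) and *long clicks* (d > boundary), a
standard proxy for user interest. Long-click proportions are summarized per
topic and per initiating search term, with high/low engagement thresholds
set by the Hampel identifier (median ± k·1.4826·MAD, k = 3) and group
comparisons by the Mann-Whitney U test.

**Sequence mining.** Within a session, maximal runs of topic views
uninterrupted by a search are windowed into contiguous subsequences of
length 2–4, counted across all sessions, and credited to the search term
immediately preceding the run. A switching score flags sequences that
merely alternate between two topics.

**Alert surveillance.** Daily term-matched search counts and media-article
counts become gap-free daily series with trailing 7-day moving averages. A
signal is a run of ≥ `min_run` days above baseline mean + k·SD; the package
reports onset, peak, elevated duration, the log-vs-media onset lag and
persistence ratio, and a pre/post alert report (vocabulary broadening,
long-click proportions, mean dwell, and drug × alert-term co-occurrence
counts).

## Worked example

Generate a 4-month synthetic dataset with a drug-safety alert on
2011-08-01 (log response lagged 5 days and sustained 20 days, media
response immediate and brief), then run the surveillance pipeline:

```sh
cat > sim.yaml <<EOF
seed: 42
start: 2011-06-01
end: 2011-09-30
sessions_per_day: 100
alert:
  date: 2011-08-01
  lag_days: 5
  elevated_duration_days: 20
  effect_multiplier: 6
EOF
clicklog simulate --config sim.yaml --out-dir fixtures

cat > drug.yaml <<EOF
name: alert_drug
seeds: [celexa, citalopram]
EOF
clicklog surveil --log fixtures/log.tsv --media fixtures/media.jsonl \
  --lexicon fixtures/lexicon.tsv --terms drug.yaml \
  --alert-date 2011-08-01 --out report.json
```

`report.json` then contains (abridged):

```json
{
 "boundary_seconds": 142.95,
 "log_signal":   {"onset": "2011-08-06", "elevated_duration_days": 20},
 "media_signal": {"onset": "2011-08-01", "elevated_duration_days": 8},
 "comparison":   {"lag_days": 5, "duration_ratio": 2.5},
 "pre_post": {
  "topics": [
   {"topic_id": "t_C_citalopram_di",
    "pre_unique_terms": 2, "post_unique_terms": 6,
    "pre_long_click_proportion": 0.916, "post_long_click_proportion": 0.500}
  ],
  "pre_mean_dwell_seconds": 1225.9, "post_mean_dwell_seconds": 475.5,
  "pre_specificity_count": 0, "post_specificity_count": 436
 }
}
```

Reading the numbers: the short/long click boundary fitted on this log is
142.95 s. The clinician-log search signal for the drug crossed its
baseline-plus-3·SD threshold on 2011-08-06 — exactly the planted 5-day lag
after the alert — and stayed elevated for 20 days, 2.5× longer than the
immediate 8-day media spike. After the alert, the drug's topics were
reached from more distinct search terms (2 → 6), long-click proportions and
mean dwell dropped (1226 s → 475 s), and searches combining the drug with
alert-specific terms ("long qt", "heart", "rhythm") rose from 0 to 436 —
the signature of clinicians checking a specific new risk.

Other commands: `clicklog validate` (log diagnostics), `clicklog annotate`
(per-query concept matches), `clicklog termset expand` (one-hop synonym
expansion), `clicklog engagement` (per-topic/per-term tables), `clicklog
sequences` (top topic-view sequences).

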