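# Methods

This note documents the models and procedures implemented in `clicklog`,
the conventions chosen where the underlying analysis admits more than one
reading, and what the synthetic-data generator does and does not emulate.

## Log model and sessionization

An event is `(session_id, institution_id, timestamp, action, payload)` with
`action ∈ {search, topic_view, subtopic_view}`; the payload is the query
string for searches and a topic identifier otherwise. Subtopic views carry
`parent_topic/suffix` so they can be folded onto their parent topic. All
timestamps in a file share one declared timezone and are kept naive; daily
and monthly aggregation uses that timezone's calendar dates.

Sessions are taken as given by the session identifier — no inactivity
splitting and no user-switch detection, which cannot be done reliably from
raw logs. Within a session events are ordered by timestamp with a **stable
tie-break on input order**: at seconds resolution ties are common, and an
unordered tie would make dwell computation nondeterministic.

## Query annotation

Queries are normalized (Unicode NFKC, lowercase, punctuation → spaces,
whitespace collapsed; idempotent by construction) and annotated by **greedy
longest-match-first, left-to-right** matching over token boundaries.
Matches never overlap; each matched term carries all concepts it maps to.
This is one concrete choice among several defensible tagging policies;
whether real pipelines handle plurals or spelling variants differently does
not change any downstream computation, which only consumes matched terms.

Term-set expansion is fixed at **one hop** (seeds → concepts → full synonym
sets). A transitive closure over the concept hierarchy is available
(`follow_hierarchy=True`) but off by default: deep closures over-broaden,
and curation is modeled as an explicit, reproducible exclusion list rather
than undocumented manual review. Multi-concept terms contribute one count
per semantic category they map to; a search matching several body systems
is counted in each (systems are not exclusive).

## Dwell times and click classification

A topic view's dwell is the time to the next event that terminates it — a
search or a view of a *different* topic. Consecutive same-topic views
(including subtopic clicks) merge into one dwell starting at the first
view. A view block still open when the session ends has no observable end
and is dropped; so are zero-length blocks, since the log transform is
undefined at 0. The initiating term of a dwell is the nearest preceding
search anywhere earlier in the session, not only the immediately adjacent
one, so chains of topic views stay attributed.

The short/long boundary is the **geometric mean** of all dwell durations:
the mean of log durations mapped back to seconds. The log base cancels, so
natural log is used. Ties at the boundary are classified short (the
definitions "less than" / "above" leave equality open; short is the
conservative side for an interest proxy). On the generator's defaults the
fitted boundary lands near 141–145 s, the scale reported for clinician
topic views.

Engagement thresholds use the Hampel identifier, median ± k·1.4826·MAD with
k = 3 (the conventional multiplier; the 1.4826 factor makes MAD consistent
for a Gaussian SD). Bounds are clamped to [0, 1] when the inputs are
proportions — detected automatically, overridable. All-equal inputs give
zero MAD; the bounds collapse and are flagged degenerate rather than
guessed.

Group comparisons of unique initiating-term counts use the Mann-Whitney U
test (scipy): exact null distribution when both groups have ≤ 8 tie-free
observations, tie-corrected normal approximation otherwise. The test suite
checks the exact branch against full enumeration and the asymptotic branch
against its nominal type-I error rate.

## Sequence mining

Runs are maximal stretches of views uninterrupted by a search, with
subtopics folded onto parents and immediately repeated topics collapsed
(subtopic clicks within one page are not navigation). Every **contiguous
window** of length 2–4 inside a run counts as one occurrence — overlapping
occurrences included — because fixed-size patterns are drawn from longer
browsing streams; counts are occurrences, not sessions. The run's
initiating search is credited to each of its windows; runs with no
preceding search count but credit no term. `max_len` defaults to 4 because
longer sequences are dominated by two-topic switching, quantified by
`switching_fraction` (the fraction of positions `i` with
`topics[i] == topics[i+2]`; 1.0 for strict alternation, 0.0 below length 3).
Ranking ties break lexicographically for determinism.

## Surveillance

Daily series are gap-free (missing days are zeros). Query matching is
event-level via annotation; media matching is document-level presence of
any term of the set (a document counts once however many mentions it has).
The 7-day moving average is **trailing**, not centered — causal, as a
surveillance statistic should be — with the first `window−1` days undefined
(NaN).

"A deviation from the mean" is operationalized as: threshold =
baseline mean + k·SD (sample SD, k = 3 default), onset = first day starting
`min_run` = 3 consecutive days strictly above threshold, elevation ends at
the first day starting `min_run` consecutive days at or below threshold,
peak = argmax from onset. The baseline is an explicit date range (typically
everything before the alert) or the whole series minus an exclusion window,
so the event being sought does not contaminate its own baseline. A zero-SD
baseline falls back to mean + 1 and is flagged. Both k and `min_run` are
exposed parameters; k = 3 with a 3-day run keeps the null false-onset rate
of the Poisson-like daily counts well under 5% (verified over 100 null
simulations in the test suite).

The pre/post alert report splits the log at the alert date (whole span by
default; a symmetric window in days is available as a sensitivity check).
Topics *reached from* drug-term searches are selected, then per topic and
window: unique initiating-term counts and long-click proportions over all
views of the topic; plus the mean dwell on those topics and the count of
searches containing a drug term together with at least one alert-specific
term ("long qt", "heart", "rhythm" in the shipped configuration).

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions for the acceptance checks.

* **Span and volume** — two years (2011-01-01..2012-12-31), Poisson 40
  sessions/day, one search per session followed by 1–6 topic/subtopic views
  (distribution (0.25, 0.30, 0.20, 0.12, 0.08, 0.05)). This is a desk-scale
  stand-in for production volumes; all statistics under test are ratios,
  thresholds, lags, or ranks that do not depend on absolute volume.
* **Dwell model** — a two-class log-normal mixture attached to search
  terms: every term is planted *all-short* (μ = 3.6 log-s ≈ 37 s) or
  *all-long* (μ = 6.3 ≈ 545 s), σ = 1.0, capped at 2 h. A balanced mixture
  puts the geometric-mean boundary near exp(4.95) ≈ 141 s and makes the
  per-term long-click proportion bimodal at ≈ 0.09 and 0.91 — the central
  empirical pattern the engagement analysis relies on. Inter-view gaps *are*
  the planted dwells, so recovery is exact up to 1-s rounding and the
  boundary's own estimation error.
* **Vocabulary** — ten body systems, each with disease/drug/device/procedure
  concepts carrying 1–3 synonym terms; searches draw a system uniformly and
  a category from the planted mix (0.70, 0.20, 0.05, 0.05). A designated
  multiword expansion cluster (essential hypertension) exercises term-set
  expansion; the alert drug, the seasonal cluster, and the sequence-motif
  disease are kept out of the background pools so their rates are controlled
  by their own channels and the planted category mix stays clean.
* **Seasonality** — the seasonal term set's search probability is modulated
  by 1 + 0.6·cos(2π(month − 1)/12), peaking in January. The peak month is
  estimated from the phase of the yearly Fourier component of monthly
  counts, which is robust where a raw argmax between two near-equal winter
  months is not.
* **Alert response** — from alert date (2011-08-24) + 10 days, for 60 days:
  drug-search probability × 8 (0.05 → 0.4 of sessions), vocabulary broadened
  3× with alert-specific term combinations, and drug-topic dwell means
  shifted by −0.15 log-units from the alert date on. The media stream
  instead spikes the day of the alert (+30 expected documents, geometric
  decay to 5% over 10 days) over a 2-docs/day baseline. The multiplier is
  set so the planted response is detectable day-accurately at desk scale;
  with ~2 matched searches/day at baseline, the 3·SD threshold sits near 6
  and the elevated rate near 16/day.
* **Determinism** — all randomness flows from one integer seed through
  named generator streams; regeneration is byte-identical, emitted files
  embed the seed in a header comment, and ground truth (term classes, daily
  matched/total counts, planted onset/duration, motif, media onset) is
  written as sidecar JSON so tests never re-derive planted values from the
  log.

**What the generator does not emulate:** natural-language queries (terms
are drawn verbatim from the lexicon, so annotation recall is 1 by
construction — tests of matching exercise correctness, not robustness to
misspellings); institution-level concentration (a uniform institution
label); user switching within sessions; correlated multi-search sessions
(each synthetic session has exactly one search); and any topic-level
relationship between engagement and initiating-term diversity. Passing
tests therefore demonstrate that the *methods* recover what they claim from
data with the assumed structure — not that real logs have that structure.

## Numerical and edge-case conventions

* Dwell durations are strictly positive; equal timestamps drop the block.
* `fraction_series` defines 0/0 = 0 (a day with no searches).
* Moving-average warm-up days are NaN and are ignored by signal detection.
* Ranking ties (patterns, burden top-10 flags) break lexicographically.
* The burden join is an inner join; conditions missing on either side are
  excluded, and an empty join is an error rather than an empty table.
* Baseline SD uses ddof = 1.

## Problem sizes in the test suite

Oracle-equivalence checks run 100 seeded random logs of up to 1,000 events;
planted-recovery checks run 20 two-year generator runs (alert lag/duration),
one two-year run (bimodality, ≥ 150 terms with ≥ 20 views each), and 100
four-month null runs (false-onset rate). The full suite completes in about
two minutes on one CPU.

## Known limitations

* The signal criterion (k·SD + run length) is one reasonable
  operationalization; other detectors (CUSUM, Farrington) are out of scope.
* Sessions are trusted as single-user; initiating-term attribution degrades
  if sessions mix users.
* No disproportionality statistics (PRR/ROR) — the alert analysis measures
  uptake, not adverse-event association.
* The annotator does no spelling correction, word-sense disambiguation, or
  negation handling; term sets inherit any ambiguity their synonyms carry.
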