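"""Seeded synthetic fixtures: lexicon, usage logs, and a media stream.

The generator emulates the statistical structure the analysis assumes, with
the ground truth recorded alongside so every stage is testable without any
proprietary data:

* sessions arrive as a daily Poisson stream; each session is one free-text
  search followed by 1-6 topic/subtopic views;
* dwell times are a two-class log-normal mixture: every search term is
  planted as *all-short* or *all-long*, and the views it initiates draw
  their dwell from the corresponding log-normal — this is what makes the
  per-term long-click proportion bimodal, the analysis' central empirical
  property;
* searches for a designated seasonal term set (influenza and its drugs)
  are modulated sinusoidally over the calendar year;
* a drug-safety alert is planted as a *delayed, sustained* response in the
  log: starting ``lag_days`` after the alert date and lasting
  ``elevated_duration_days``, the rate of drug-term searches is multiplied,
  the search vocabulary broadens (including alert-specific terms such as
  "long qt"), and dwell means on the drug's topics shift;
* the media stream instead spikes *immediately* at the alert and decays
  geometrically within days;
* one session channel plants a dominant disease -> drug -> drug topic-view
  motif for sequence-mining tests.

All randomness flows from one integer seed; regeneration is byte-identical
and every emitted file embeds the seed in a header comment.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .lexicon import Category, Lexicon, TermSet, dump_lexicon
from .log_io import Action, LogEvent, write_log
from .surveillance import MediaDoc, write_media

BODY_SYSTEMS = (
    "cardiovascular",
    "respiratory",
    "digestive",
    "endocrine",
    "hemic and immune",
    "integumentary",
    "musculoskeletal",
    "mouth and jaw",
    "nervous",
    "urogenital",
)

_CAT_CODE = {
    Category.DISEASE_SYMPTOM: "ds",
    Category.DRUG: "rx",
    Category.DEVICE: "dv",
    Category.PROCEDURE: "pr",
}


@dataclass(frozen=True)
class DwellModel:
    """Two-class log-normal dwell mixture (natural-log scale, seconds).

    Defaults put the geometric-mean boundary of a balanced mixture near
    exp((3.6+6.3)/2) ~ 141 s, the scale observed for clinician topic views.
    """

    mu_short: float = 3.6
    mu_long: float = 6.3
    sigma: float = 1.0
    cap_seconds: float = 7200.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class SeasonalModel:
    """Sinusoidal yearly modulation of the seasonal term set's search rate."""

    amplitude: float = 0.6
    peak_month: int = 1

    def factor(self, month: int) -> float:
        return 1.0 + self.amplitude * math.cos(
            2 * math.pi * (month - self.peak_month) / 12.0
        )


@dataclass(frozen=True)
class AlertModel:
    """Planted drug-safety-alert response in the usage log."""

    date: date = date(2011, 8, 24)
    lag_days: int = 10
    effect_multiplier: float = 8.0
    elevated_duration_days: int = 60
    vocab_broadening_factor: int = 3
    dwell_shift: float = -0.15  # additive, log-seconds, post-alert drug views
    enabled: bool = True

    def __post_init__(self):
        if self.lag_days < 0:
            raise ValueError("lag_days must be >= 0")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be positive")


@dataclass(frozen=True)
class MediaModel:
    """Planted immediate, short-lived media response."""

    spike_day_offset: int = 0
    spike_height: float = 30.0
    decay_days: int = 10
    baseline_matched_per_day: float = 2.0
    background_docs_per_day: float = 5.0

    def spike(self, days_since_onset: int) -> float:
        if days_since_onset < 0 or self.spike_height <= 0:
            return 0.0
        r = 0.05 ** (1.0 / self.decay_days)  # decayed to 5% at decay_days
        return self.spike_height * r**days_since_onset


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic stream (all rates per day)."""

    seed: int = 0
    start: date = date(2011, 1, 1)
    end: date = date(2012, 12, 31)
    sessions_per_day: float = 40.0
    views_per_session_probs: tuple[float, ...] = (0.25, 0.30, 0.20, 0.12, 0.08, 0.05)
    dwell: DwellModel = field(default_factory=DwellModel)
    seasonal: SeasonalModel = field(default_factory=SeasonalModel)
    alert: AlertModel = field(default_factory=AlertModel)
    media: MediaModel = field(default_factory=MediaModel)
    long_term_fraction: float = 0.5
    drug_search_prob: float = 0.05
    seasonal_search_prob: float = 0.10
    motif_search_prob: float = 0.03
    subtopic_prob: float = 0.10
    category_mix: tuple[float, float, float, float] = (0.70, 0.20, 0.05, 0.05)
    n_institutions: int = 25

    def __post_init__(self):
        if self.sessions_per_day < 0:
            raise ValueError("sessions_per_day must be >= 0")
        if self.end < self.start:
            raise ValueError("end before start")
        if abs(sum(self.views_per_session_probs) - 1.0) > 1e-9:
            raise ValueError("views_per_session_probs must sum to 1")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class GroundTruth:
    """Planted quantities recorded at generation time."""

    seed: int
    term_class: dict[str, str]  # term -> "short" | "long"
    daily_matched: dict[str, int]  # iso date -> drug-matched searches
    daily_total: dict[str, int]  # iso date -> all searches
    alert_date: str | None
    alert_onset: str | None  # alert date + lag
    alert_lag_days: int
    alert_duration_days: int
    seasonal_peak_month: int
    category_mix: dict[str, float]
    motif_topics: tuple[str, ...]
    drug_base_terms: tuple[str, ...]
    drug_broadened_terms: tuple[str, ...]
    seasonal_terms: tuple[str, ...]
    media_onset: str | None = None
    media_daily_matched: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["motif_topics"] = list(self.motif_topics)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["motif_topics"] = tuple(d["motif_topics"])
        d["drug_base_terms"] = tuple(d["drug_base_terms"])
        d["drug_broadened_terms"] = tuple(d["drug_broadened_terms"])
        d["seasonal_terms"] = tuple(d["seasonal_terms"])
        return cls(**d)


@dataclass
class _World:
    """Deterministic vocabulary/topic layout derived from a config."""

    lexicon: Lexicon
    # background pool: system -> category -> [(term, concept)]
    background: dict[str, dict[Category, list[tuple[str, str]]]]
    system_term_sets: dict[str, TermSet]
    topic_of_concept: dict[str, str]
    system_topics: dict[str, list[str]]
    drug_base_terms: tuple[str, ...]
    drug_broadened_terms: tuple[str, ...]
    drug_topics: tuple[str, ...]
    seasonal_terms: tuple[str, ...]
    seasonal_topics: tuple[str, ...]
    motif_term: str
    motif_topics: tuple[str, ...]
    term_class: dict[str, str]
    hypertension_cluster: tuple[str, frozenset[str]]  # (seed term, full synonym set)


_SPECIFICITY_COMBOS = (
    "celexa long qt",
    "citalopram heart",
    "celexa rhythm",
    "citalopram long qt",
    "celexa dose increase",
    "citalopram overdose risk",
    "celexa qt monitoring",
    "citalopram rhythm warning",
)

_CONCEPTS_PER_SYSTEM = {
    Category.DISEASE_SYMPTOM: 3,
    Category.DRUG: 2,
    Category.DEVICE: 1,
    Category.PROCEDURE: 1,
}


def build_world(config: GeneratorConfig) -> _World:
    """Construct the vocabulary, lexicon, topics and planted term classes.

    Deterministic in ``config.seed`` and independent of the log/media RNG
    streams, so :func:`gen_lexicon` and :func:`gen_logs` always agree.
    """
    rng = np.random.default_rng([config.seed % (2**31), 101])
    term_rows: list[tuple[str, str, Category | None, str | None]] = []
    background: dict[str, dict[Category, list[tuple[str, str]]]] = {}
    topic_of_concept: dict[str, str] = {}
    system_topics: dict[str, list[str]] = {}

    def add_concept(concept: str, terms: list[str], cat: Category | None, parent=None):
        for t in terms:
            term_rows.append((concept, t, cat, parent))

    for system in BODY_SYSTEMS:
        abbr = system.replace(" ", "")[:4]
        root = f"C_{abbr}_root"
        add_concept(root, [f"{system} system"], None)
        background[system] = {}
        system_topics[system] = []
        for cat, n in _CONCEPTS_PER_SYSTEM.items():
            code = _CAT_CODE[cat]
            background[system][cat] = []
            for i in range(n):
                concept = f"C_{abbr}_{code}{i}"
                base = f"{abbr}{code}{i}"
                n_syn = int(rng.integers(1, 4))
                terms = [base] + [f"{base}{suffix}" for suffix in "abc"[: n_syn - 1]]
                add_concept(concept, terms, cat, parent=root)
                topic = f"t_{concept}"
                topic_of_concept[concept] = topic
                system_topics[system].append(topic)
                background[system][cat] += [(t, concept) for t in terms]

    # hypertension expansion cluster (multiword synonyms; part of the
    # cardiovascular disease pool)
    htn_terms = ["essential hypertension nos", "hypertensive disease", "high blood pressure"]
    add_concept("C_hypertensive_disease", htn_terms, Category.DISEASE_SYMPTOM,
                parent="C_card_root")
    topic_of_concept["C_hypertensive_disease"] = "t_C_hypertensive_disease"
    system_topics["cardiovascular"].append("t_C_hypertensive_disease")
    background["cardiovascular"][Category.DISEASE_SYMPTOM] += [
        (t, "C_hypertensive_disease") for t in htn_terms
    ]

    # alert drug (its search rate is driven by the alert channel, so it is
    # kept out of the background pool and the body-system term sets)
    add_concept("C_citalopram", ["celexa", "citalopram"], Category.DRUG)
    drug_topics = ("t_C_citalopram_di", "t_C_citalopram_pdi")
    drug_base = ("celexa", "citalopram")
    n_broadened = max(0, (config.alert.vocab_broadening_factor - 1) * len(drug_base))
    drug_broadened = _SPECIFICITY_COMBOS[:n_broadened]

    # seasonal cluster
    add_concept("C_influenza", ["influenza", "flu"], Category.DISEASE_SYMPTOM)
    add_concept("C_oseltamivir", ["tamiflu", "oseltamivir"], Category.DRUG)
    seasonal_terms = ("influenza", "flu", "tamiflu", "oseltamivir")
    seasonal_topics = (
        "t_C_influenza",
        "t_C_oseltamivir",
        system_topics["respiratory"][0],
        system_topics["respiratory"][1],
    )

    # planted dominant motif: disease topic followed by two drug topics
    add_concept("C_cellulitis", ["cellulitis"], Category.DISEASE_SYMPTOM)
    add_concept("C_clindamycin", ["clindamycin"], Category.DRUG)
    motif_topics = ("t_C_cellulitis", "t_C_clindamycin_di", "t_C_clindamycin_sys")

    lexicon = Lexicon(
        term_to_concepts=_rows_to_term_map(term_rows),
        concept_category={
            c: cat for c, _, cat, _ in term_rows if cat is not None
        },
        hierarchy=frozenset(
            (parent, c) for c, _, _, parent in term_rows if parent is not None
        ),
    )
    lexicon.validate()

    system_term_sets = {
        system: TermSet(
            name=system,
            terms=frozenset(t for pool in background[system].values() for t, _ in pool),
        )
        for system in BODY_SYSTEMS
    }

    # plant every search term as all-short or all-long; the alert drug's base
    # terms are forced long so the planted post-alert dwell shift is visible
    all_terms = sorted(
        {t for pools in background.values() for pool in pools.values() for t, _ in pool}
        | set(drug_broadened)
        | set(seasonal_terms)
        | {"cellulitis"}
    )
    term_class = {
        t: ("long" if rng.random() < config.long_term_fraction else "short")
        for t in all_terms
    }
    for t in drug_base:
        term_class[t] = "long"

    return _World(
        lexicon=lexicon,
        background=background,
        system_term_sets=system_term_sets,
        topic_of_concept=topic_of_concept,
        system_topics=system_topics,
        drug_base_terms=drug_base,
        drug_broadened_terms=tuple(drug_broadened),
        drug_topics=drug_topics,
        seasonal_terms=seasonal_terms,
        seasonal_topics=seasonal_topics,
        motif_term="cellulitis",
        motif_topics=motif_topics,
        term_class=term_class,
        hypertension_cluster=("essential hypertension nos", frozenset(htn_terms)),
    )


def _rows_to_term_map(rows) -> dict[str, frozenset[str]]:
    m: dict[str, set[str]] = {}
    for concept, term, _, _ in rows:
        m.setdefault(term, set()).add(concept)
    return {t: frozenset(cs) for t, cs in m.items()}


def gen_lexicon(config: GeneratorConfig) -> Lexicon:
    """The synthetic lexicon for a config (deterministic in the seed)."""
    return build_world(config).lexicon


def drug_term_set(config: GeneratorConfig) -> TermSet:
    """The alert drug's term set (base synonyms), for surveillance runs."""
    world = build_world(config)
    return TermSet(name="alert_drug", terms=frozenset(world.drug_base_terms))


def seasonal_term_set(config: GeneratorConfig) -> TermSet:
    world = build_world(config)
    return TermSet(name="seasonal", terms=frozenset(world.seasonal_terms))


def gen_logs(config: GeneratorConfig) -> tuple[list[LogEvent], GroundTruth]:
    """Generate the usage log and its ground truth.

    Each session: one search (channel drawn among alert-drug / seasonal /
    motif / background) followed by 1-6 views whose inter-event gaps are the
    planted dwell draws.  The last view of a session has no terminating
    event, so final-view truncation occurs naturally.
    """
    alert = config.alert
    if alert.enabled and not (config.start <= alert.date <= config.end):
        raise ValueError(
            f"alert date {alert.date} outside log span {config.start}..{config.end}"
        )
    world = build_world(config)
    rng = np.random.default_rng([config.seed % (2**31), 202])

    effect_start = alert.date + timedelta(days=alert.lag_days)
    effect_end = effect_start + timedelta(days=alert.elevated_duration_days)
    view_counts = np.arange(1, 7)

    events: list[LogEvent] = []
    daily_matched: dict[str, int] = {}
    daily_total: dict[str, int] = {}
    session_counter = 0
    cats = list(_CONCEPTS_PER_SYSTEM)

    for day_idx in range(config.n_days):
        day = config.start + timedelta(days=day_idx)
        n_sessions = rng.poisson(config.sessions_per_day)
        if n_sessions == 0:
            continue
        in_effect = alert.enabled and effect_start <= day < effect_end
        p_drug = config.drug_search_prob * (alert.effect_multiplier if in_effect else 1.0)
        p_seas = config.seasonal_search_prob * config.seasonal.factor(day.month)
        p_motif = config.motif_search_prob
        total_special = p_drug + p_seas + p_motif
        if total_special > 0.95:  # keep a background remainder
            scale = 0.95 / total_special
            p_drug, p_seas, p_motif = (p * scale for p in (p_drug, p_seas, p_motif))

        day_start = datetime.combine(day, time.min)
        starts = rng.integers(0, 86400, size=n_sessions)
        channel_draws = rng.random(n_sessions)
        for s in range(n_sessions):
            session_counter += 1
            sid = f"s{session_counter:08d}"
            inst = f"inst{int(rng.integers(config.n_institutions))}"
            t = day_start + timedelta(seconds=int(starts[s]))
            r = channel_draws[s]
            matched = False
            if r < p_drug:
                matched = True
                vocab = world.drug_base_terms + (
                    world.drug_broadened_terms if in_effect else ()
                )
                term = vocab[int(rng.integers(len(vocab)))]
                topic_pool = world.drug_topics
                n_views = int(rng.choice(view_counts, p=config.views_per_session_probs))
                topics = [topic_pool[int(i)] for i in rng.integers(len(topic_pool), size=n_views)]
            elif r < p_drug + p_seas:
                term = world.seasonal_terms[int(rng.integers(len(world.seasonal_terms)))]
                n_views = int(rng.choice(view_counts, p=config.views_per_session_probs))
                pool = world.seasonal_topics
                topics = [pool[int(i)] for i in rng.integers(len(pool), size=n_views)]
            elif r < p_drug + p_seas + p_motif:
                term = world.motif_term
                topics = list(world.motif_topics)
            else:
                system = BODY_SYSTEMS[int(rng.integers(len(BODY_SYSTEMS)))]
                cat = cats[int(rng.choice(len(cats), p=config.category_mix))]
                pool = world.background[system][cat]
                term, concept = pool[int(rng.integers(len(pool)))]
                n_views = int(rng.choice(view_counts, p=config.views_per_session_probs))
                sys_pool = world.system_topics[system]
                topics = [world.topic_of_concept[concept]] + [
                    sys_pool[int(i)] for i in rng.integers(len(sys_pool), size=n_views - 1)
                ]

            iso = day.isoformat()
            daily_total[iso] = daily_total.get(iso, 0) + 1
            if matched:
                daily_matched[iso] = daily_matched.get(iso, 0) + 1

            events.append(LogEvent(sid, inst, t, Action.SEARCH, term))
            t += timedelta(seconds=int(rng.integers(2, 12)))

            mu = (
                config.dwell.mu_long
                if world.term_class.get(term, "short") == "long"
                else config.dwell.mu_short
            )
            if matched and alert.enabled and day >= alert.date:
                mu += alert.dwell_shift
            dwell_draws = np.clip(
                np.round(rng.lognormal(mu, config.dwell.sigma, size=len(topics))),
                1.0,
                config.dwell.cap_seconds,
            ).astype(int)
            sub_draws = rng.random(len(topics))
            for j, topic in enumerate(topics):
                events.append(LogEvent(sid, inst, t, Action.TOPIC_VIEW, topic))
                if j == len(topics) - 1:
                    break  # final view: dangling, dwell unobservable
                dwell = int(dwell_draws[j])
                if sub_draws[j] < config.subtopic_prob and dwell >= 2:
                    gap1 = max(1, dwell // 2)
                    events.append(
                        LogEvent(
                            sid,
                            inst,
                            t + timedelta(seconds=gap1),
                            Action.SUBTOPIC_VIEW,
                            f"{topic}/s{j}",
                        )
                    )
                t += timedelta(seconds=dwell)

    truth = GroundTruth(
        seed=config.seed,
        term_class=dict(sorted(world.term_class.items())),
        daily_matched=daily_matched,
        daily_total=daily_total,
        alert_date=alert.date.isoformat() if alert.enabled else None,
        alert_onset=effect_start.isoformat() if alert.enabled else None,
        alert_lag_days=alert.lag_days,
        alert_duration_days=alert.elevated_duration_days,
        seasonal_peak_month=config.seasonal.peak_month,
        category_mix={
            cat.value: p for cat, p in zip(_CONCEPTS_PER_SYSTEM, config.category_mix)
        },
        motif_topics=world.motif_topics,
        drug_base_terms=world.drug_base_terms,
        drug_broadened_terms=world.drug_broadened_terms,
        seasonal_terms=world.seasonal_terms,
    )
    return events, truth


_MATCHED_TEMPLATES = (
    "regulators issued a new advisory describing celexa and abnormal heart rhythm",
    "coverage of the citalopram dose warning continued across health desks",
    "patient groups reacted to the celexa safety communication this week",
)
_BACKGROUND_TEMPLATES = (
    "markets closed mixed as earnings season continued",
    "local weather brought rain to the coast over the weekend",
    "city council debated the transit budget late into the evening",
)


def gen_media(config: GeneratorConfig) -> tuple[list[MediaDoc], dict]:
    """Generate the dated media-document stream and its planted bookkeeping.

    A low-rate baseline of drug-mentioning documents plus an additive spike
    starting at the alert date + ``spike_day_offset``, decaying geometrically
    over ``decay_days``; background documents never mention the drug.
    """
    rng = np.random.default_rng([config.seed % (2**31), 303])
    media = config.media
    onset = (
        config.alert.date + timedelta(days=media.spike_day_offset)
        if config.alert.enabled
        else None
    )
    docs: list[MediaDoc] = []
    daily_matched: dict[str, int] = {}
    doc_counter = 0
    for day_idx in range(config.n_days):
        day = config.start + timedelta(days=day_idx)
        spike = media.spike((day - onset).days) if onset is not None else 0.0
        n_matched = rng.poisson(media.baseline_matched_per_day + spike)
        n_background = rng.poisson(media.background_docs_per_day)
        daily_matched[day.isoformat()] = int(n_matched)
        day_start = datetime.combine(day, time.min)
        for kind, n, templates in (
            ("drug", n_matched, _MATCHED_TEMPLATES),
            ("bg", n_background, _BACKGROUND_TEMPLATES),
        ):
            for _ in range(n):
                doc_counter += 1
                ts = day_start + timedelta(seconds=int(rng.integers(0, 86400)))
                docs.append(
                    MediaDoc(
                        title=f"article {doc_counter}",
                        timestamp=ts,
                        url=f"https://example.invalid/{kind}/{doc_counter}",
                        content=templates[int(rng.integers(len(templates)))],
                    )
                )
    docs.sort(key=lambda d: d.timestamp)
    return docs, {
        "media_onset": onset.isoformat() if onset is not None else None,
        "media_daily_matched": daily_matched,
    }


def simulate(config: GeneratorConfig, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Emit log.tsv, lexicon.tsv, media.jsonl and truth.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = build_world(config)
    events, truth = gen_logs(config)
    docs, media_truth = gen_media(config)
    truth.media_onset = media_truth["media_onset"]
    truth.media_daily_matched = media_truth["media_daily_matched"]

    paths = {
        "lexicon": out / "lexicon.tsv",
        "log": out / "log.tsv",
        "media": out / "media.jsonl",
        "truth": out / "truth.json",
    }
    dump_lexicon(world.lexicon, paths["lexicon"], header_comment=f"seed={config.seed}")
    write_log(events, paths["log"], header_comment=f"seed={config.seed}")
    write_media(docs, paths["media"], header_comment=f"seed={config.seed}")
    paths["truth"].write_text(truth.to_json(), encoding="utf-8")
    return paths


def load_config(path: Union[str, Path]) -> GeneratorConfig:
    """Load a GeneratorConfig from YAML (nested sections mirror the
    dataclasses; dates as ISO strings)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key in ("start", "end"):
        if key in kwargs and isinstance(kwargs[key], str):
            kwargs[key] = date.fromisoformat(kwargs[key])
    for key, cls in (
        ("dwell", DwellModel),
        ("seasonal", SeasonalModel),
        ("alert", AlertModel),
        ("media", MediaModel),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            section = dict(kwargs[key])
            if key == "alert" and isinstance(section.get("date"), str):
                section["date"] = date.fromisoformat(section["date"])
            kwargs[key] = cls(**section)
    for key in ("views_per_session_probs", "category_mix"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return GeneratorConfig(**kwargs)
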