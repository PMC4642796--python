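from __future__ import annotations

import sys
from datetime import date, datetime
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from clicklog.lexicon import Category, Lexicon
from clicklog.log_io import Action, LogEvent
from clicklog.synthetic_data import AlertModel, GeneratorConfig


@pytest.fixture
def tiny_lexicon() -> Lexicon:
    """Hand-built lexicon with the hypertension expansion cluster, a drug,
    and an ambiguous short/long term pair (diabetes / diabetes insipidus)."""
    rows = {
        "essential hypertension nos": {"C_htn"},
        "hypertensive disease": {"C_htn"},
        "high blood pressure": {"C_htn"},
        "celexa": {"C_cit"},
        "citalopram": {"C_cit"},
        "tamiflu": {"C_oselt"},
        "diabetes": {"C_dm"},
        "diabetes insipidus": {"C_di"},
        "influenza": {"C_flu"},
    }
    lex = Lexicon(
        term_to_concepts={t: frozenset(cs) for t, cs in rows.items()},
        concept_category={
            "C_htn": Category.DISEASE_SYMPTOM,
            "C_cit": Category.DRUG,
            "C_oselt": Category.DRUG,
            "C_dm": Category.DISEASE_SYMPTOM,
            "C_di": Category.DISEASE_SYMPTOM,
            "C_flu": Category.DISEASE_SYMPTOM,
        },
        hierarchy=frozenset({("C_dm", "C_di")}),
    )
    lex.validate()
    return lex


def ev(sid: str, t: int, action: Action, payload: str,
       base: datetime = datetime(2011, 8, 24, 9, 0, 0)) -> LogEvent:
    """Shorthand event at `base + t seconds`."""
    from datetime import timedelta

    return LogEvent(sid, "inst1", base + timedelta(seconds=t), action, payload)


@pytest.fixture
def make_event():
    return ev


@pytest.fixture
def fast_config() -> GeneratorConfig:
    """90-day generator config used where the 2-year default is overkill."""
    return GeneratorConfig(
        seed=11,
        start=date(2011, 8, 1),
        end=date(2011, 10, 29),
        sessions_per_day=100.0,
        alert=AlertModel(date=date(2011, 8, 24), lag_days=10,
                         elevated_duration_days=30, effect_multiplier=5.0),
    )
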