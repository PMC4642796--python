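from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clicklog.lexicon import (
    Category,
    Lexicon,
    LexiconError,
    TermSet,
    annotate_query,
    burden_join,
    category_distribution,
    dump_lexicon,
    expand_term_set,
    load_lexicon,
    match_events,
    monthly_volume,
    normalize,
)
from clicklog.log_io import Action
from clicklog.synthetic_data import GeneratorConfig, gen_lexicon
from oracles import annotate_oracle, one_hop_closure_oracle


# ---------------------------------------------------------------- normalize

@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Celexa  (citalopram)", "celexa citalopram"),
        ("", ""),
        ("ESSENTIAL hypertension, NOS!", "essential hypertension nos"),
        ("a_b c", "a b c"),
    ],
)
def test_normalize_examples(raw, expected):
    assert normalize(raw) == expected


@settings(max_examples=1000, deadline=None)
@given(st.text())
def test_normalize_idempotent(s):
    assert normalize(normalize(s)) == normalize(s)


# ------------------------------------------------------------- load / dump

def test_load_three_line_fixture(tmp_path):
    p = tmp_path / "lex.tsv"
    p.write_text(
        "C_cit\tCelexa\tdrug\t\n"
        "C_cit\tcitalopram\tdrug\t\n"
        "C_flu\tinfluenza\tdisease_symptom\t\n"
    )
    lex = load_lexicon(p)
    assert lex.concept_terms["C_cit"] == frozenset({"celexa", "citalopram"})
    assert lex.concept_category["C_cit"] is Category.DRUG


def test_contradictory_category_is_error(tmp_path):
    p = tmp_path / "lex.tsv"
    p.write_text("C1\ta\tdrug\t\nC1\tb\tdevice\t\n")
    with pytest.raises(LexiconError, match="C1"):
        load_lexicon(p)


def test_hierarchy_cycle_is_error(tmp_path):
    p = tmp_path / "lex.tsv"
    p.write_text("C1\ta\tdrug\tC2\nC2\tb\tdrug\tC1\n")
    with pytest.raises(LexiconError, match="cycle"):
        load_lexicon(p)


@pytest.mark.parametrize("seed", [0, 7, 123])
def test_generated_lexicon_round_trips(tmp_path, seed):
    lex = gen_lexicon(GeneratorConfig(seed=seed))
    p = tmp_path / "lex.tsv"
    dump_lexicon(lex, p)
    again = load_lexicon(p)
    assert again.term_to_concepts == lex.term_to_concepts
    assert again.concept_category == lex.concept_category
    assert again.hierarchy == lex.hierarchy


# --------------------------------------------------------------- annotation

def test_annotate_simple_drug_match(tiny_lexicon):
    ann = annotate_query("tamiflu dose", tiny_lexicon)
    assert [m.term for m in ann.matches] == ["tamiflu"]
    assert ann.matches[0].concept_ids == frozenset({"C_oselt"})


def test_annotate_hypertension_cluster(tiny_lexicon):
    ann = annotate_query("Essential Hypertension NOS", tiny_lexicon)
    assert len(ann.matches) == 1
    assert ann.matches[0].concept_ids == frozenset({"C_htn"})


def test_annotate_prefers_longest_match(tiny_lexicon):
    ann = annotate_query("diabetes insipidus workup", tiny_lexicon)
    assert [m.term for m in ann.matches] == ["diabetes insipidus"]


def test_annotate_matches_are_sorted_and_token_aligned(tiny_lexicon):
    ann = annotate_query("influenza and celexa and diabetes", tiny_lexicon)
    assert [m.term for m in ann.matches] == ["influenza", "celexa", "diabetes"]
    for m in ann.matches:
        assert ann.normalized[m.start : m.end] == m.term
    starts = [m.start for m in ann.matches]
    assert starts == sorted(starts)
    ends = [m.end for m in ann.matches]
    assert all(e1 <= s2 for e1, s2 in zip(ends, starts[1:]))  # non-overlap


def test_annotate_equals_bruteforce_oracle_on_random_fixture():
    rng = np.random.default_rng(7)
    vocab = [f"w{i}" for i in range(30)]
    terms = set()
    while len(terms) < 60:
        n = int(rng.integers(1, 4))
        terms.add(" ".join(rng.choice(vocab, size=n)))
    lex = Lexicon(
        term_to_concepts={t: frozenset({f"C{i}"}) for i, t in enumerate(sorted(terms))},
        concept_category={},
        hierarchy=frozenset(),
    )
    for _ in range(500):
        q = " ".join(rng.choice(vocab, size=int(rng.integers(1, 10))))
        got = [m.term for m in annotate_query(q, lex).matches]
        assert got == annotate_oracle(q, terms)


# ---------------------------------------------------------------- term sets

def test_expand_hypertension_cluster(tiny_lexicon):
    ts = expand_term_set({"essential hypertension nos"}, tiny_lexicon)
    assert ts.terms == frozenset(
        {"essential hypertension nos", "hypertensive disease", "high blood pressure"}
    )


def test_expand_unknown_seed_survives_alone(tiny_lexicon):
    ts = expand_term_set({"notaterm"}, tiny_lexicon)
    assert ts.terms == frozenset({"notaterm"})


def test_expand_exclusions_and_empty_error(tiny_lexicon):
    ts = expand_term_set(
        {"essential hypertension nos"}, tiny_lexicon,
        exclusions={"high blood pressure"},
    )
    assert "high blood pressure" not in ts.terms
    with pytest.raises(ValueError):
        expand_term_set(
            {"celexa"}, tiny_lexicon, exclusions={"celexa", "citalopram"}
        )


def test_expand_follow_hierarchy_pulls_descendants(tiny_lexicon):
    flat = expand_term_set({"diabetes"}, tiny_lexicon)
    deep = expand_term_set({"diabetes"}, tiny_lexicon, follow_hierarchy=True)
    assert flat.terms == frozenset({"diabetes"})
    assert deep.terms == frozenset({"diabetes", "diabetes insipidus"})


@pytest.mark.parametrize("seed", range(5))
def test_expand_equals_one_hop_closure_oracle(seed):
    rng = np.random.default_rng(seed)
    lex = gen_lexicon(GeneratorConfig(seed=seed))
    all_terms = sorted(lex.term_to_concepts)
    seeds = set(rng.choice(all_terms, size=4, replace=False))
    exclusions = set(rng.choice(all_terms, size=2, replace=False)) - seeds
    got = expand_term_set(seeds, lex, exclusions).terms
    assert got == one_hop_closure_oracle(seeds, lex, exclusions)
    assert got >= (seeds - exclusions)  # superset property


# ------------------------------------------------------- matching & volumes

def test_match_events_finds_the_flu_search(tiny_lexicon, make_event):
    events = [
        make_event("s1", 0, Action.SEARCH, "influenza treatment"),
        make_event("s2", 1, Action.SEARCH, "celexa"),
        make_event("s3", 2, Action.SEARCH, "xyzzy"),
        make_event("s1", 3, Action.TOPIC_VIEW, "influenza"),  # views never match
    ]
    ts = TermSet(name="flu", terms=frozenset({"influenza"}))
    assert match_events(events, ts, tiny_lexicon) == [events[0]]
    assert match_events([], ts, tiny_lexicon) == []


def test_monthly_volume_zero_fills_span(tiny_lexicon, make_event):
    from datetime import datetime

    events = [
        make_event("s1", 0, Action.SEARCH, "influenza", base=datetime(2011, 1, 5)),
        make_event("s2", 0, Action.SEARCH, "influenza", base=datetime(2011, 1, 20)),
        make_event("s3", 0, Action.SEARCH, "influenza", base=datetime(2011, 2, 3)),
        make_event("s4", 0, Action.SEARCH, "celexa", base=datetime(2011, 4, 1)),
    ]
    ts = TermSet(name="flu", terms=frozenset({"influenza"}))
    vol = monthly_volume(events, ts, tiny_lexicon)
    assert vol == {(2011, 1): 2, (2011, 2): 1, (2011, 3): 0, (2011, 4): 0}
    assert sum(vol.values()) == len(match_events(events, ts, tiny_lexicon))


def test_category_distribution_counts_and_sharing(tiny_lexicon, make_event):
    events = [
        make_event("s1", 0, Action.SEARCH, "influenza"),
        make_event("s2", 1, Action.SEARCH, "diabetes"),
        make_event("s3", 2, Action.SEARCH, "hypertensive disease"),
        make_event("s4", 3, Action.SEARCH, "celexa"),
    ]
    sys_a = TermSet(name="A", terms=frozenset({"influenza", "diabetes", "celexa"}))
    sys_b = TermSet(name="B", terms=frozenset({"celexa", "hypertensive disease"}))
    dist = category_distribution(events, [sys_a, sys_b], tiny_lexicon)
    assert dist["A"][Category.DISEASE_SYMPTOM] == pytest.approx(2 / 3)
    assert dist["A"][Category.DRUG] == pytest.approx(1 / 3)
    # celexa is counted in both systems
    assert dist["B"][Category.DRUG] == pytest.approx(1 / 2)
    for system in dist.values():
        assert sum(system.values()) == pytest.approx(1.0)


@pytest.mark.parametrize("peak", [1, 4, 7, 12])
def test_seasonal_peak_month_on_exact_sinusoid(peak):
    import math

    from clicklog.lexicon import seasonal_peak_month

    volumes = {
        (2011, m): round(1000 * (1 + 0.6 * math.cos(2 * math.pi * (m - peak) / 12)))
        for m in range(1, 13)
    }
    assert seasonal_peak_month(volumes) == peak


# -------------------------------------------------------------- burden join

def test_burden_join_flags_match_sort_oracle():
    rng = np.random.default_rng(3)
    conditions = [f"cond{i}" for i in range(12)]
    volumes = {c: int(rng.integers(1, 1000)) for c in conditions}
    burden = {c: (float(rng.integers(1, 10**6)), float(rng.integers(1, 10**4)))
              for c in conditions}
    df = burden_join(volumes, burden, top_n=10)
    for col, flag in [("cost", "top_cost"), ("discharges", "top_discharges"),
                      ("query_volume", "top_queries")]:
        expected = set(
            sorted(conditions, key=lambda c: (-df.set_index("condition")[col][c], c))[:10]
        )
        assert set(df[df[flag]]["condition"]) == expected


def test_burden_join_single_condition_all_flags_true():
    df = burden_join({"sepsis": 10}, {"sepsis": (1.0, 2.0)})
    assert bool(df.top_cost.all() and df.top_discharges.all() and df.top_queries.all())


def test_burden_join_inner_join_and_empty_error():
    df = burden_join({"a": 1, "b": 2}, {"b": (1.0, 1.0), "c": (2.0, 2.0)})
    assert list(df.condition) == ["b"]
    with pytest.raises(ValueError):
        burden_join({"a": 1}, {"b": (1.0, 1.0)})
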