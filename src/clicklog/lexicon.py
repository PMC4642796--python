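"""Dictionary-based concept annotation of free-text queries.

A lexicon maps normalized terms to biomedical concepts, concepts to one of
four semantic categories (diseases and symptoms, drugs, medical devices,
procedures), and concepts to each other through parent-child edges.  Queries
are annotated by greedy longest-match-first, left-to-right, token-boundary
matching over the normalized string; each matched term carries every concept
it maps to.

Term sets (body systems, condition-code groups, drug synonym sets) are built
by one-hop expansion: each seed term is looked up in the lexicon, and the
full synonym set of every concept it maps to is pulled in.  Curation is
mechanized as an explicit exclusion list.
"""

from __future__ import annotations

import math
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from functools import cached_property
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

from .log_io import Action, LogEvent


class Category(str, Enum):
    DISEASE_SYMPTOM = "disease_symptom"
    DRUG = "drug"
    DEVICE = "device"
    PROCEDURE = "procedure"
    NONE = "none"


#: the four substantive semantic categories (excludes NONE)
SEMANTIC_CATEGORIES = (
    Category.DISEASE_SYMPTOM,
    Category.DRUG,
    Category.DEVICE,
    Category.PROCEDURE,
)

_NON_WORD = re.compile(r"[\W_]+", flags=re.UNICODE)


def normalize(text: str) -> str:
    """Canonical form used for all term matching.

    Unicode NFKC, lowercase, punctuation mapped to spaces, whitespace
    collapsed and trimmed.  Idempotent.
    """
    text = unicodedata.normalize("NFKC", text).lower()
    return _NON_WORD.sub(" ", text).strip()


class LexiconError(ValueError):
    pass


@dataclass
class Lexicon:
    """Term-concept mappings with synonymy, categories, and hierarchy."""

    term_to_concepts: dict[str, frozenset[str]]
    concept_category: dict[str, Category]
    hierarchy: frozenset[tuple[str, str]]  # (parent, child) edges

    @cached_property
    def concept_terms(self) -> dict[str, frozenset[str]]:
        """Inverse of ``term_to_concepts``: concept -> its synonym terms."""
        inv: dict[str, set[str]] = {}
        for term, concepts in self.term_to_concepts.items():
            for c in concepts:
                inv.setdefault(c, set()).add(term)
        return {c: frozenset(ts) for c, ts in inv.items()}

    @cached_property
    def max_term_tokens(self) -> int:
        return max((len(t.split()) for t in self.term_to_concepts), default=0)

    @cached_property
    def children(self) -> dict[str, frozenset[str]]:
        ch: dict[str, set[str]] = {}
        for parent, child in self.hierarchy:
            ch.setdefault(parent, set()).add(child)
        return {p: frozenset(cs) for p, cs in ch.items()}

    def category_of(self, concept_id: str) -> Category:
        return self.concept_category.get(concept_id, Category.NONE)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`LexiconError` on failure."""
        for c in self.concept_category:
            if c not in self.concept_terms:
                raise LexiconError(f"concept {c!r} has a category but no terms")
        nodes = {n for edge in self.hierarchy for n in edge}
        graph: dict[str, set[str]] = {n: set() for n in nodes}
        for parent, child in self.hierarchy:
            graph[child].add(parent)
        try:
            list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise LexiconError(f"hierarchy contains a cycle: {exc}") from None


def load_lexicon(path: Union[str, Path]) -> Lexicon:
    """Load a lexicon from TSV with columns
    ``concept_id, term, category, parent_concept_id`` (last two may be empty).

    Terms are normalized on load.  A concept assigned two different
    categories, or a cyclic hierarchy, is an error.
    """
    term_to_concepts: dict[str, set[str]] = {}
    concept_category: dict[str, Category] = {}
    hierarchy: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise LexiconError(
                    f"line {line_number}: expected 4 columns, got {len(parts)}"
                )
            concept_id, term, category, parent = parts
            term = normalize(term)
            if not term:
                raise LexiconError(f"line {line_number}: empty term")
            term_to_concepts.setdefault(term, set()).add(concept_id)
            if category:
                cat = Category(category)
                prev = concept_category.get(concept_id)
                if prev is not None and prev is not cat:
                    raise LexiconError(
                        f"line {line_number}: concept {concept_id!r} assigned "
                        f"both {prev.value!r} and {cat.value!r}"
                    )
                concept_category[concept_id] = cat
            if parent:
                hierarchy.add((parent, concept_id))
    lex = Lexicon(
        term_to_concepts={t: frozenset(cs) for t, cs in term_to_concepts.items()},
        concept_category=concept_category,
        hierarchy=frozenset(hierarchy),
    )
    lex.validate()
    return lex


def dump_lexicon(
    lexicon: Lexicon, path: Union[str, Path], header_comment: str | None = None
) -> None:
    """Write a lexicon in the TSV format :func:`load_lexicon` reads.

    Output is deterministically ordered so equal lexicons produce identical
    bytes; ``load_lexicon(dump_lexicon(L)) == L``.
    """
    parents: dict[str, list[str]] = {}
    for parent, child in lexicon.hierarchy:
        parents.setdefault(child, []).append(parent)
    for ps in parents.values():
        ps.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#concept_id\tterm\tcategory\tparent_concept_id\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for concept in sorted(lexicon.concept_terms):
            cat = lexicon.concept_category.get(concept)
            cat_str = cat.value if cat is not None else ""
            terms = sorted(lexicon.concept_terms[concept])
            ps = parents.get(concept, [])
            # one row per term; extra parents (rare) repeat the first term
            n_rows = max(len(terms), len(ps))
            for i in range(n_rows):
                term = terms[i] if i < len(terms) else terms[0]
                parent = ps[i] if i < len(ps) else ""
                fh.write(f"{concept}\t{term}\t{cat_str}\t{parent}\n")


@dataclass(frozen=True)
class Match:
    """One annotated span; offsets index the normalized query string."""

    start: int
    end: int
    term: str
    concept_ids: frozenset[str]


@dataclass(frozen=True)
class AnnotatedQuery:
    raw: str
    normalized: str
    matches: tuple[Match, ...]

    @property
    def matched_terms(self) -> set[str]:
        return {m.term for m in self.matches}


def annotate_query(query: str, lexicon: Lexicon) -> AnnotatedQuery:
    """Annotate a free-text query against the lexicon.

    Greedy longest-match-first, left-to-right over tokens of the normalized
    query; matches never overlap and always align to token boundaries.
    """
    normalized = normalize(query)
    tokens = [(m.start(), m.end(), m.group()) for m in re.finditer(r"\S+", normalized)]
    matches: list[Match] = []
    i = 0
    n = len(tokens)
    max_span = lexicon.max_term_tokens
    while i < n:
        found = None
        for span in range(min(max_span, n - i), 0, -1):
            candidate = normalized[tokens[i][0] : tokens[i + span - 1][1]]
            concepts = lexicon.term_to_concepts.get(candidate)
            if concepts is not None:
                found = Match(tokens[i][0], tokens[i + span - 1][1], candidate, concepts)
                i += span
                break
        if found is not None:
            matches.append(found)
        else:
            i += 1
    return AnnotatedQuery(raw=query, normalized=normalized, matches=tuple(matches))


class QueryAnnotator:
    """Memoizing wrapper around :func:`annotate_query` for bulk matching."""

    def __init__(self, lexicon: Lexicon):
        self.lexicon = lexicon
        self._cache: dict[str, AnnotatedQuery] = {}

    def __call__(self, query: str) -> AnnotatedQuery:
        ann = self._cache.get(query)
        if ann is None:
            ann = annotate_query(query, self.lexicon)
            self._cache[query] = ann
        return ann


@dataclass(frozen=True)
class TermSet:
    """A curated set of synonym terms representing a clinical entity.

    ``terms`` is already net of ``exclusions``; the exclusion list is kept
    for provenance (it mechanizes manual review of over-broad expansions).
    """

    name: str
    terms: frozenset[str]
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.terms & self.exclusions:
            raise ValueError("terms and exclusions must be disjoint")
        if not self.terms:
            raise ValueError(f"term set {self.name!r} is empty after exclusion")


def expand_term_set(
    seed_terms: Iterable[str],
    lexicon: Lexicon,
    exclusions: Iterable[str] = (),
    name: str = "",
    follow_hierarchy: bool = False,
) -> TermSet:
    """One-hop expansion: seeds -> their concepts -> those concepts' synonyms.

    Seeds unknown to the lexicon survive unchanged.  With
    ``follow_hierarchy=True`` the synonyms of all descendant concepts are
    pulled in as well (off by default: deep closures tend to over-broaden,
    which the exclusion list would otherwise have to undo).
    """
    seeds = {normalize(t) for t in seed_terms}
    excl = frozenset(normalize(t) for t in exclusions)
    terms = set(seeds)
    concepts: set[str] = set()
    for s in seeds:
        concepts |= lexicon.term_to_concepts.get(s, frozenset())
    if follow_hierarchy:
        frontier = list(concepts)
        while frontier:
            c = frontier.pop()
            for child in lexicon.children.get(c, ()):
                if child not in concepts:
                    concepts.add(child)
                    frontier.append(child)
    for c in concepts:
        terms |= lexicon.concept_terms.get(c, frozenset())
    return TermSet(name=name, terms=frozenset(terms - excl), exclusions=excl)


def load_term_set(path: Union[str, Path], lexicon: Lexicon | None = None) -> TermSet:
    """Load a term set from YAML: ``name``, ``seeds``, optional ``exclusions``
    and ``expand`` flag (requires a lexicon when true)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    seeds = cfg["seeds"]
    exclusions = cfg.get("exclusions", [])
    if cfg.get("expand", False):
        if lexicon is None:
            raise ValueError("term-set expansion requested but no lexicon given")
        return expand_term_set(seeds, lexicon, exclusions, name=cfg.get("name", ""))
    excl = frozenset(normalize(t) for t in exclusions)
    return TermSet(
        name=cfg.get("name", ""),
        terms=frozenset(normalize(t) for t in seeds) - excl,
        exclusions=excl,
    )


def match_events(
    events: Iterable[LogEvent],
    term_set: TermSet,
    lexicon: Lexicon,
    annotator: QueryAnnotator | None = None,
) -> list[LogEvent]:
    """Search events whose annotation contains any term of the set.

    Matching happens at the annotation level, so multiword terms respect
    token boundaries and a longer lexicon term shadows a shorter one.
    """
    ann = annotator or QueryAnnotator(lexicon)
    out = []
    for e in events:
        if e.action is Action.SEARCH and ann(e.payload).matched_terms & term_set.terms:
            out.append(e)
    return out


def monthly_volume(
    events: Sequence[LogEvent],
    term_set: TermSet,
    lexicon: Lexicon,
) -> dict[tuple[int, int], int]:
    """Matched-search counts per calendar month, zero-filled over the span
    of the input events."""
    if not events:
        return {}
    matched = match_events(events, term_set, lexicon)
    start = min(e.timestamp for e in events)
    end = max(e.timestamp for e in events)
    months = pd.period_range(start=start, end=end, freq="M")
    counts = Counter((e.timestamp.year, e.timestamp.month) for e in matched)
    return {(p.year, p.month): counts.get((p.year, p.month), 0) for p in months}


def category_distribution(
    events: Iterable[LogEvent],
    system_term_sets: Sequence[TermSet],
    lexicon: Lexicon,
) -> dict[str, dict[Category, float]]:
    """Per-system distribution of matched-term semantic categories.

    A search matching several systems is counted in each (systems are not
    exclusive).  Within a system, each matched term belonging to the system's
    set contributes one count per substantive category among its concepts.
    Proportions per system sum to 1 when the system has any matches.
    """
    ann = QueryAnnotator(lexicon)
    counts: dict[str, Counter] = {ts.name: Counter() for ts in system_term_sets}
    for e in events:
        if e.action is not Action.SEARCH:
            continue
        matches = ann(e.payload).matches
        for ts in system_term_sets:
            for m in matches:
                if m.term not in ts.terms:
                    continue
                cats = {lexicon.category_of(c) for c in m.concept_ids}
                for cat in cats & set(SEMANTIC_CATEGORIES):
                    counts[ts.name][cat] += 1
    out: dict[str, dict[Category, float]] = {}
    for ts in system_term_sets:
        c = counts[ts.name]
        total = sum(c.values())
        out[ts.name] = {
            cat: (c[cat] / total if total else 0.0) for cat in SEMANTIC_CATEGORIES
        }
    return out


def seasonal_peak_month(volumes: Mapping[tuple[int, int], int]) -> int:
    """Calendar month (1-12) at which a yearly-periodic volume series peaks.

    Estimated from the phase of the yearly Fourier component of the monthly
    counts, which is robust to month-length differences and count noise where
    a raw argmax between two near-equal winter months is not.
    """
    if not volumes or not any(volumes.values()):
        raise ValueError("no volume to estimate a seasonal peak from")
    x = sum(
        v * math.cos(2 * math.pi * (m - 1) / 12) for (_, m), v in volumes.items()
    )
    y = sum(
        v * math.sin(2 * math.pi * (m - 1) / 12) for (_, m), v in volumes.items()
    )
    phase = math.atan2(y, x)
    return round(phase / (2 * math.pi) * 12) % 12 + 1


def burden_join(
    query_volumes: Mapping[str, int],
    burden_table: Mapping[str, tuple[float, float]],
    top_n: int = 10,
) -> pd.DataFrame:
    """Join per-condition query volumes with a national burden table.

    ``burden_table`` maps condition -> (aggregate cost, discharges).  The
    result is the inner join with boolean flags for top-``top_n`` membership
    on each axis (ties broken by condition label for determinism).
    """
    common = sorted(set(query_volumes) & set(burden_table))
    if not common:
        raise ValueError("no conditions shared between query volumes and burden table")
    df = pd.DataFrame(
        {
            "condition": common,
            "cost": [burden_table[c][0] for c in common],
            "discharges": [burden_table[c][1] for c in common],
            "query_volume": [query_volumes[c] for c in common],
        }
    )
    for col, flag in (
        ("cost", "top_cost"),
        ("discharges", "top_discharges"),
        ("query_volume", "top_queries"),
    ):
        order = df.sort_values(
            [col, "condition"], ascending=[False, True]
        ).index[:top_n]
        df[flag] = df.index.isin(order)
    return df
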