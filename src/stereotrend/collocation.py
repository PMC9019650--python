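"""Collocate extraction under windowed co-occurrence rules, and MI filtering.

A *target* (node) term — possibly multiword, e.g. "senior citizen" — is
located in tokenized documents; the words within a six-content-word window
on either side are its collocates.  Three rules govern the window:

* articles ({a, an, the} by default) are skipped and never consume span
  budget, nor are they collocates themselves;
* the tokens of the target occurrence are never their own collocates;
* the window may cross sentence boundaries, except that a target which is
  the first word of its sentence takes no collocates from the preceding
  sentence.

Co-occurrence counts per (target, collocate, stratum) are combined with
marginal frequencies into a Mutual Information score,

    MI = log2( f(node, collocate) * N / (f(node) * f(collocate) * W) ),

with W = 2 * span the window size, following the english-corpora.org
convention.  Collocates with MI >= 3 (inclusive) are conventionally said to
be semantically bonded to the node and are retained.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .corpus import CorpusStats, TokenizedDocument, stratum_key
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

AGE_BASED = "age_based"
ROLE_BASED = "role_based"

#: Age-marked references to older adults (the published example terms).
DEFAULT_AGE_TERMS = (
    "aged",
    "elderly",
    "old people",
    "senior citizen",
    "older adult",
    "golden ager",
)

#: Familial-role references to older adults (the full published list).
DEFAULT_ROLE_TERMS = (
    "grandparent",
    "grandparents",
    "grandfather",
    "grandmother",
    "grandpa",
    "grandma",
    "granddad",
    "granny",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetLexicon:
    """Target terms mapped to a framing category (age_based | role_based).

    Terms are stored lowercase; multiword terms as space-joined strings but
    matched as token sequences.  No term may belong to both categories.
    """

    framing_of: Mapping[str, str]

    def __post_init__(self):
        for term, framing in self.framing_of.items():
            if term != term.lower():
                raise ConfigurationError(f"target term {term!r} must be lowercase")
            if not term.strip():
                raise ConfigurationError("empty target term")
            if framing not in (AGE_BASED, ROLE_BASED):
                raise ConfigurationError(f"unknown framing {framing!r} for term {term!r}")

    @property
    def terms(self) -> list[str]:
        return sorted(self.framing_of)

    def framings(self) -> list[str]:
        return sorted(set(self.framing_of.values()))

    def terms_for(self, framing: str) -> list[str]:
        return sorted(t for t, f in self.framing_of.items() if f == framing)

    @classmethod
    def from_pairs(cls, age_terms: Iterable[str] = (), role_terms: Iterable[str] = ()) -> "TargetLexicon":
        mapping: dict[str, str] = {}
        for t in age_terms:
            mapping[t.lower()] = AGE_BASED
        for t in role_terms:
            if t.lower() in mapping:
                raise ConfigurationError(f"term {t!r} assigned to both framings")
            mapping[t.lower()] = ROLE_BASED
        return cls(mapping)

    @classmethod
    def default(cls) -> "TargetLexicon":
        return cls.from_pairs(DEFAULT_AGE_TERMS, DEFAULT_ROLE_TERMS)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetLexicon":
        """Read a two-column TSV: term <TAB> framing."""
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                term, framing = line.split("\t")
                if term.lower() in mapping and mapping[term.lower()] != framing:
                    raise ConfigurationError(f"term {term!r} assigned to both framings")
                mapping[term.lower()] = framing
        return cls(mapping)


@dataclass(frozen=True)
class WindowConfig:
    """Window and filtering rules for collocate extraction."""

    span: int = 6
    excluded_articles: frozenset[str] = frozenset({"a", "an", "the"})
    cross_sentence: str = "allow"  # "allow" | "within_sentence"
    mi_threshold: float = 3.0
    min_cooccurrence: int = 1

    def __post_init__(self):
        if self.span < 1:
            raise ConfigurationError("span must be >= 1")
        if not math.isfinite(self.mi_threshold):
            raise ConfigurationError("mi_threshold must be finite")
        if self.min_cooccurrence < 1:
            raise ConfigurationError("min_cooccurrence must be >= 1")
        if self.cross_sentence not in ("allow", "within_sentence"):
            raise ConfigurationError(f"unknown cross_sentence policy {self.cross_sentence!r}")


class Occurrence(NamedTuple):
    """One matched target-term site inside a tokenized document."""

    sent_idx: int
    tok_idx: int
    term: str
    framing: str
    sentence_initial: bool


@dataclass(frozen=True)
class CollocateRecord:
    target: str
    collocate: str
    decade: int
    genre: str | None
    count: int
    target_freq: int
    collocate_freq: int
    stratum_n: int
    mi: float


@dataclass
class CooccurrenceTable:
    """Raw co-occurrence counts plus target occurrence tallies per stratum."""

    counts: dict = field(default_factory=dict)  # (term, collocate, stratum) -> count
    target_freqs: dict = field(default_factory=dict)  # (term, stratum) -> occurrence count
    by_genre: bool = False


# ---------------------------------------------------------------------------
# Occurrence matching
# ---------------------------------------------------------------------------


def _term_index(lexicon: TargetLexicon) -> dict[str, list[tuple[tuple[str, ...], str, str]]]:
    """first token -> [(token tuple, term string, framing)], longest first."""
    index: dict[str, list[tuple[tuple[str, ...], str, str]]] = defaultdict(list)
    for term, framing in lexicon.framing_of.items():
        toks = tuple(term.split())
        index[toks[0]].append((toks, term, framing))
    for entries in index.values():
        entries.sort(key=lambda e: -len(e[0]))
    return dict(index)


def find_target_occurrences(
    doc: TokenizedDocument, lexicon: TargetLexicon
) -> list[Occurrence]:
    """Locate target terms, longest-match-first, left-to-right.

    Each token position contributes to at most one occurrence: after a
    match, scanning resumes past the matched tokens.
    """
    if not lexicon.framing_of:
        raise ConfigurationError("empty target lexicon")
    index = _term_index(lexicon)
    out: list[Occurrence] = []
    for s_idx, sent in enumerate(doc.sentences):
        i = 0
        n = len(sent)
        while i < n:
            entries = index.get(sent[i])
            matched = False
            if entries:
                for toks, term, framing in entries:
                    if sent[i : i + len(toks)] == toks:
                        out.append(Occurrence(s_idx, i, term, framing, sentence_initial=(i == 0)))
                        i += len(toks)
                        matched = True
                        break
            if not matched:
                i += 1
    return out


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def extract_window(
    doc: TokenizedDocument, site: Occurrence, cfg: WindowConfig
) -> list[str]:
    """Collocate tokens within ``cfg.span`` content words of the target.

    Articles are skipped without consuming span budget and are never
    returned.  If the target is sentence-initial, no tokens from before its
    sentence are returned; with ``cross_sentence="within_sentence"`` the
    window never leaves the target's sentence.
    """
    left = _walk_window(doc, site, cfg, direction=-1)
    right = _walk_window(doc, site, cfg, direction=+1)
    return left + right


def _walk_window(
    doc: TokenizedDocument, site: Occurrence, cfg: WindowConfig, direction: int
) -> list[str]:
    """Collect up to span non-article tokens in one direction."""
    sentences = doc.sentences
    term_len = len(site.term.split())
    within_only = cfg.cross_sentence == "within_sentence"
    stop_at_sentence = within_only or (direction < 0 and site.sentence_initial)

    s = site.sent_idx
    t = site.tok_idx - 1 if direction < 0 else site.tok_idx + term_len
    got: list[str] = []
    budget = cfg.span
    while budget > 0:
        if t < 0 or t >= len(sentences[s]):
            if stop_at_sentence:
                break
            s += direction
            if s < 0 or s >= len(sentences):
                break
            t = len(sentences[s]) - 1 if direction < 0 else 0
            continue
        tok = sentences[s][t]
        t += direction
        if tok in cfg.excluded_articles:
            continue
        got.append(tok)
        budget -= 1
    if direction < 0:
        got.reverse()
    return got


# ---------------------------------------------------------------------------
# Counting, MI, filtering
# ---------------------------------------------------------------------------


def count_collocates(
    docs: Iterable[TokenizedDocument],
    lexicon: TargetLexicon,
    cfg: WindowConfig,
    by_genre: bool = False,
) -> CooccurrenceTable:
    """Count (target, collocate, stratum) co-occurrences over all windows."""
    table = CooccurrenceTable(by_genre=by_genre)
    for doc in docs:
        key = stratum_key(doc, by_genre)
        for site in find_target_occurrences(doc, lexicon):
            tkey = (site.term, key)
            table.target_freqs[tkey] = table.target_freqs.get(tkey, 0) + 1
            for tok in extract_window(doc, site, cfg):
                ckey = (site.term, tok, key)
                table.counts[ckey] = table.counts.get(ckey, 0) + 1
    return table


def compute_mi(
    cooccurrence_count: int,
    target_freq: int,
    collocate_freq: int,
    stratum_n: int,
    span: int,
) -> float:
    """Mutual Information in bits: log2(cooc * N / (f_t * f_c * 2*span))."""
    if min(cooccurrence_count, target_freq, collocate_freq, stratum_n) <= 0:
        raise DataError("MI undefined for zero or negative counts")
    w = 2 * span
    return math.log2(cooccurrence_count * stratum_n / (target_freq * collocate_freq * w))


def build_collocate_records(
    table: CooccurrenceTable,
    stats: CorpusStats,
    cfg: WindowConfig,
) -> list[CollocateRecord]:
    """Attach marginal frequencies and MI to every raw co-occurrence count.

    ``collocate_freq`` is the word's corpus frequency in the stratum;
    ``target_freq`` the number of matched occurrence sites of the term.
    """
    records: list[CollocateRecord] = []
    for (term, collocate, key), count in sorted(table.counts.items()):
        decade, genre = (key if table.by_genre else (key, None))
        tf = table.target_freqs[(term, key)]
        cf = stats.freq(key, collocate)
        n = stats.n(key)
        records.append(
            CollocateRecord(
                target=term,
                collocate=collocate,
                decade=decade,
                genre=genre,
                count=count,
                target_freq=tf,
                collocate_freq=cf,
                stratum_n=n,
                mi=compute_mi(count, tf, cf, n, cfg.span),
            )
        )
    return records


def filter_collocates(
    records: Iterable[CollocateRecord],
    cfg: WindowConfig,
    exclusion: Mapping[str, set[str]] | set[str] | None = None,
) -> list[CollocateRecord]:
    """Keep records with MI >= threshold (inclusive), count >= minimum, and
    collocate not on the exclusion list.

    ``exclusion`` may be a global word set or a per-target mapping; it
    stands in for the human relevance screen.
    """
    kept: list[CollocateRecord] = []
    dropped_mi = dropped_count = dropped_excl = 0
    for rec in records:
        if isinstance(exclusion, Mapping):
            excluded = rec.collocate in exclusion.get(rec.target, ())
        elif exclusion is not None:
            excluded = rec.collocate in exclusion
        else:
            excluded = False
        if excluded:
            dropped_excl += 1
        elif rec.mi < cfg.mi_threshold:
            dropped_mi += 1
        elif rec.count < cfg.min_cooccurrence:
            dropped_count += 1
        else:
            kept.append(rec)
    logger.info(
        "filter_collocates: retained %d, dropped %d (MI < %.3g), %d (count < %d), %d (excluded)",
        len(kept), dropped_mi, cfg.mi_threshold, dropped_count, cfg.min_cooccurrence, dropped_excl,
    )
    return kept


def extract_collocates(
    docs: Sequence[TokenizedDocument],
    lexicon: TargetLexicon,
    cfg: WindowConfig,
    stats: CorpusStats | None = None,
    by_genre: bool = False,
    exclusion: Mapping[str, set[str]] | set[str] | None = None,
) -> tuple[list[CollocateRecord], CooccurrenceTable]:
    """Full extraction: windows -> counts -> MI -> filters.

    Returns the retained records and the raw co-occurrence table (whose
    ``target_freqs`` feed the narrative-score weighting downstream).
    """
    from .corpus import corpus_frequencies

    if stats is None:
        stats = corpus_frequencies(docs, by_genre=by_genre)
    table = count_collocates(docs, lexicon, cfg, by_genre=by_genre)
    records = build_collocate_records(table, stats, cfg)
    return filter_collocates(records, cfg, exclusion), table


def records_to_frame(records: Iterable[CollocateRecord]) -> pd.DataFrame:
    """Records as a tidy DataFrame (CSV layout: target, collocate, decade,
    genre, count, target_freq, collocate_freq, N, mi)."""
    return pd.DataFrame(
        [
            {
                "target": r.target,
                "collocate": r.collocate,
                "decade": r.decade,
                "genre": r.genre if r.genre is not None else "",
                "count": r.count,
                "target_freq": r.target_freq,
                "collocate_freq": r.collocate_freq,
                "N": r.stratum_n,
                "mi": r.mi,
            }
            for r in records
        ]
    )


def read_exclusion_list(path: str | Path) -> set[str]:
    """One word per line; '#' comments and blank lines ignored."""
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            w = line.strip().lower()
            if w and not w.startswith("#"):
                words.add(w)
    return words
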