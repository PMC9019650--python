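"""Corpus reading, tokenization, sentence segmentation, and frequency tables.

A corpus is a collection of documents, each stamped with a calendar year
(default range 1810-2019) and a genre label.  Documents are binned into
decades (1810, 1820, ..., 2010 — 21 bins over the default range) and
reduced to lowercased tokens grouped into sentences.  Per-stratum token
totals and word marginal frequencies feed the Mutual Information score in
the collocation stage.

Tokenization is deliberately simple and deterministic: whitespace split,
edge punctuation stripped, sentence boundaries at terminal ``.``/``!``/``?``
with a small abbreviation guard list.  Collocates downstream are surface
forms, not lemmas.
"""

from __future__ import annotations

import csv
import json
import logging
import string
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

DEFAULT_YEAR_RANGE: tuple[int, int] = (1810, 2019)

#: Canonical genre vocabulary (open: other labels are accepted).
CANONICAL_GENRES = ("newspapers", "magazines", "fiction", "nonfiction")

#: Abbreviations whose trailing period does not end a sentence.  The token
#: keeps its period so "mr." is distinguishable from the word "mr".
ABBREVIATIONS = frozenset(
    {
        "mr.", "mrs.", "ms.", "dr.", "prof.", "st.", "jr.", "sr.", "rev.",
        "gen.", "col.", "capt.", "lt.", "sgt.", "vs.", "etc.", "e.g.",
        "i.e.", "no.", "vol.", "fig.", "ca.", "approx.",
    }
)

_EDGE_PUNCT = string.punctuation + "‘’“”–—…"
_CLOSERS = "\"')]}’”"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Document:
    """One corpus text with provenance metadata."""

    doc_id: str
    year: int
    genre: str
    text: str

    def validate(self, year_range: tuple[int, int] = DEFAULT_YEAR_RANGE) -> None:
        lo, hi = year_range
        if not (lo <= self.year <= hi):
            raise DataError(
                f"document {self.doc_id!r}: year {self.year} outside [{lo}, {hi}]"
            )
        if not self.genre:
            raise DataError(f"document {self.doc_id!r}: empty genre")
        if not self.text.strip():
            raise DataError(f"document {self.doc_id!r}: empty text")


@dataclass(frozen=True)
class TokenizedDocument:
    """A document reduced to lowercased sentence-segmented tokens.

    ``decade`` is the decade bin label: floor(year/10)*10, so 1815 -> 1810
    and 2019 -> 2010.
    """

    doc_id: str
    decade: int
    genre: str
    sentences: tuple[tuple[str, ...], ...]

    @property
    def token_count(self) -> int:
        return sum(len(s) for s in self.sentences)


@dataclass
class CorpusStats:
    """Per-stratum token totals N and word marginal frequencies.

    A stratum key is a decade (int) or a ``(decade, genre)`` pair,
    depending on how the stats were built.
    """

    totals: dict = field(default_factory=dict)  # stratum -> N
    marginals: dict = field(default_factory=dict)  # stratum -> Counter

    @property
    def strata(self) -> list:
        return sorted(self.totals)

    def n(self, stratum) -> int:
        return self.totals[stratum]

    def freq(self, stratum, word: str) -> int:
        return self.marginals.get(stratum, Counter())[word]


# ---------------------------------------------------------------------------
# Reading and writing corpora
# ---------------------------------------------------------------------------

DIALECTS = ("jsonl", "tsv", "wordline")


def read_corpus(
    path: str | Path,
    dialect: str = "jsonl",
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> Iterator[Document]:
    """Yield validated :class:`Document` objects from a corpus file.

    Malformed records (missing year/text, unparseable year, out-of-range
    year) are skipped with a logged warning; an unreadable file or unknown
    dialect is fatal.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown corpus dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise OSError(f"corpus file not found: {path}")
    if dialect == "jsonl":
        records = _iter_jsonl(path)
    elif dialect == "tsv":
        records = _iter_tsv(path)
    else:
        records = _iter_wordline(path)

    n_skipped = 0
    for lineno, rec in records:
        try:
            doc = Document(
                doc_id=str(rec["doc_id"]),
                year=int(rec["year"]),
                genre=str(rec["genre"]),
                text=str(rec["text"]),
            )
            doc.validate(year_range)
        except (KeyError, TypeError, ValueError, DataError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed record at %s:%s: %s", path.name, lineno, exc)
            continue
        yield doc
    if n_skipped:
        logger.info("read_corpus: skipped %d malformed record(s) in %s", n_skipped, path.name)


def _iter_jsonl(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                logger.warning("skipping unparseable JSON at %s:%d: %s", path.name, lineno, exc)
                yield lineno, {}


def _iter_tsv(path: Path):
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "year" not in reader.fieldnames:
            raise ConfigurationError(f"TSV corpus {path} lacks a header row with a 'year' column")
        for lineno, row in enumerate(reader, 2):
            yield lineno, {k: v for k, v in row.items() if v is not None and v != ""}


def _iter_wordline(path: Path):
    """COHA-database style: '##doc_id<TAB>year<TAB>genre' headers, one token per line."""
    current: dict | None = None
    header_line = 0
    tokens: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                if current is not None:
                    current["text"] = " ".join(tokens)
                    yield header_line, current
                parts = line[2:].split("\t")
                current = dict(zip(("doc_id", "year", "genre"), parts))
                header_line = lineno
                tokens = []
            elif line.strip():
                tokens.append(line.strip())
    if current is not None:
        current["text"] = " ".join(tokens)
        yield header_line, current


def write_corpus(docs: Iterable[Document], path: str | Path) -> int:
    """Write documents as canonical JSON Lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {"doc_id": doc.doc_id, "year": doc.year, "genre": doc.genre, "text": doc.text},
                    ensure_ascii=False,
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Tokenization and sentence segmentation
# ---------------------------------------------------------------------------


def decade_bin(year: int) -> int:
    """Decade bin label: floor(year/10)*10."""
    return (year // 10) * 10


def tokenize_and_segment(
    doc: Document,
    decade_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> TokenizedDocument:
    """Lowercase, strip edge punctuation, split into sentences, bin the decade.

    Sentence boundaries fall after tokens ending in ``.``/``!``/``?``
    (possibly followed by closing quotes/brackets), unless the token is a
    guarded abbreviation such as ``mr.`` — which keeps its period.
    """
    lo, hi = decade_range
    if not (lo <= doc.year <= hi):
        raise DataError(f"document {doc.doc_id!r}: year {doc.year} outside [{lo}, {hi}]")
    sentences: list[tuple[str, ...]] = []
    current: list[str] = []
    for raw in doc.text.split():
        low = raw.lower()
        if low in ABBREVIATIONS:
            current.append(low)
            continue
        core = low.strip(_EDGE_PUNCT)
        if core:
            current.append(core)
        if low.rstrip(_CLOSERS).endswith((".", "!", "?")) and current:
            sentences.append(tuple(current))
            current = []
    if current:
        sentences.append(tuple(current))
    return TokenizedDocument(
        doc_id=doc.doc_id,
        decade=decade_bin(doc.year),
        genre=doc.genre,
        sentences=tuple(sentences),
    )


def tokenize_corpus(
    docs: Iterable[Document],
    decade_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> list[TokenizedDocument]:
    return [tokenize_and_segment(d, decade_range) for d in docs]


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------


def stratum_key(doc: TokenizedDocument, by_genre: bool):
    return (doc.decade, doc.genre) if by_genre else doc.decade


def corpus_frequencies(
    docs: Iterable[TokenizedDocument],
    by_genre: bool = False,
) -> CorpusStats:
    """Per-stratum token totals and word marginal frequencies.

    Strata are decades, or (decade, genre) pairs when ``by_genre`` is set.
    Raises :class:`DataError` on an empty stream.
    """
    stats = CorpusStats()
    seen = False
    for doc in docs:
        seen = True
        key = stratum_key(doc, by_genre)
        counter = stats.marginals.setdefault(key, Counter())
        for sent in doc.sentences:
            counter.update(sent)
        stats.totals[key] = stats.totals.get(key, 0) + doc.token_count
    if not seen:
        raise DataError("corpus_frequencies: empty document stream")
    return stats
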