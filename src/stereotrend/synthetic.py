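"""Synthetic corpora, rating lexicons, and topic corpora with known truth.

The generator emulates the statistical structure the pipeline is built to
measure: decade-stamped documents in which target terms (age-based and
role-based references to older adults) sit inside sentences whose
surrounding words are drawn from valence-stratified word pools, with the
pool mixture chosen so the expected in-window mean rating follows a linear
per-decade trajectory — a separate intercept and slope per framing.
Articles are interspersed at a configurable rate to exercise the rule that
articles never consume window span.

Two design constraints keep the measurement faithful:

* pool words are framing-specific and appear only inside target windows, so
  a collocate's corpus frequency comes entirely from its windows;
* filler text is sized so that the expected Mutual Information of even a
  once-co-occurring pool word clears the MI >= 3 retention threshold —
  otherwise the filter would select collocates by count and distort the
  recovered valence trajectory.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field


import numpy as np

from .collocation import DEFAULT_AGE_TERMS, DEFAULT_ROLE_TERMS, AGE_BASED, ROLE_BASED
from .corpus import Document
from .errors import ConfigurationError
from .valence import ValenceLexicon

RATING_BINS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Study conditions for a generated corpus.

    Defaults emulate the published setting: 21 decade bins 1810-2010, four
    genres, and per-framing valence trajectories with the published
    intercepts and per-decade slopes (role-based 3.13 - 0.0067 t, age-based
    3.04 - 0.023 t on the 1-5 scale, t the decade index from 1810).
    """

    decades: tuple[int, ...] = tuple(range(1810, 2011, 10))
    genres: tuple[str, ...] = ("newspapers", "magazines", "fiction", "nonfiction")
    docs_per_decade_per_genre: int = 24
    sentences_per_doc: int = 10
    filler_sentence_length: int = 18
    target_sentence_rate: float = 0.125
    age_terms: tuple[str, ...] = DEFAULT_AGE_TERMS
    role_terms: tuple[str, ...] = DEFAULT_ROLE_TERMS
    trajectories: dict = field(
        default_factory=lambda: {AGE_BASED: (3.04, -0.023), ROLE_BASED: (3.13, -0.0067)}
    )
    words_per_pool: int = 80
    window_words_per_side: int = 6
    article_rate: float = 0.25
    sentence_initial_rate: float = 0.1
    filler_vocab_size: int = 400
    rater_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for framing, (b0, b1) in self.trajectories.items():
            for i in range(len(self.decades)):
                m = b0 + b1 * i
                if not (1.0 <= m <= 5.0):
                    raise ConfigurationError(
                        f"trajectory for {framing} leaves [1, 5] at decade index {i} (mean {m:.3f})"
                    )
        if not (0 <= self.article_rate < 1):
            raise ConfigurationError("article_rate must be in [0, 1)")
        if self.words_per_pool < 1 or self.filler_vocab_size < 1:
            raise ConfigurationError("pools and filler vocabulary must be non-empty")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score recovery of the downstream estimates."""

    trajectories: dict  # framing -> (intercept, slope per decade index)
    word_ratings: dict  # word -> true integer rating
    pools: dict  # (framing, rating) -> tuple of words
    rater_noise_sd: float
    seed: int


def _make_pools(spec: SyntheticCorpusSpec) -> dict:
    pools = {}
    for framing, tag in ((AGE_BASED, "age"), (ROLE_BASED, "rol")):
        for r in RATING_BINS:
            pools[(framing, r)] = tuple(
                f"{tag}{r}w{i:03d}" for i in range(spec.words_per_pool)
            )
    return pools


def _filler_vocab(spec: SyntheticCorpusSpec) -> tuple[str, ...]:
    return tuple(f"fill{i:04d}" for i in range(spec.filler_vocab_size))


def generate_corpus(spec: SyntheticCorpusSpec) -> tuple[list[Document], GroundTruth]:
    """Generate decade-binned documents with planted valence trajectories.

    Each target sentence embeds one target term with exactly
    ``window_words_per_side`` pool words on each side (none on the left for
    sentence-initial targets), sampled so their expected mean rating equals
    the framing's trajectory at that decade; articles are inserted inside
    the window region without displacing pool words from the six-content-
    word span.  Remaining sentences are filler drawn from a disjoint
    vocabulary.
    """
    rng = np.random.default_rng(spec.seed)
    pools = _make_pools(spec)
    filler = _filler_vocab(spec)
    articles = ("the", "a", "an")
    framings = sorted(spec.trajectories)
    terms = {AGE_BASED: spec.age_terms, ROLE_BASED: spec.role_terms}

    word_ratings = {w: r for (f, r), ws in pools.items() for w in ws}
    for w in filler:
        word_ratings[w] = 3

    docs: list[Document] = []
    doc_no = 0
    for d_idx, decade in enumerate(spec.decades):
        for genre in spec.genres:
            for _ in range(spec.docs_per_decade_per_genre):
                year = decade + int(rng.integers(0, 10))
                year = min(year, 2019)
                sentences = []
                for _s in range(spec.sentences_per_doc):
                    if rng.random() < spec.target_sentence_rate:
                        framing = framings[int(rng.integers(0, len(framings)))]
                        sentences.append(
                            _target_sentence(
                                rng, spec, pools, framing, terms[framing], d_idx, articles
                            )
                        )
                    else:
                        idx = rng.integers(0, len(filler), size=spec.filler_sentence_length)
                        sentences.append(" ".join(filler[i] for i in idx) + ".")
                doc_no += 1
                docs.append(
                    Document(
                        doc_id=f"syn{doc_no:06d}",
                        year=year,
                        genre=genre,
                        text=" ".join(sentences),
                    )
                )
    truth = GroundTruth(
        trajectories=dict(spec.trajectories),
        word_ratings=word_ratings,
        pools=pools,
        rater_noise_sd=spec.rater_noise_sd,
        seed=spec.seed,
    )
    return docs, truth


def _draw_pool_words(rng, spec, pools, framing, d_idx, n):
    """Sample n words whose expected rating equals the trajectory mean by
    mixing the two adjacent integer rating bins."""
    b0, b1 = spec.trajectories[framing]
    m = b0 + b1 * d_idx
    lo = min(int(math.floor(m)), 4)
    frac = m - lo
    out = []
    for _ in range(n):
        r = lo + 1 if rng.random() < frac else lo
        pool = pools[(framing, r)]
        out.append(pool[int(rng.integers(0, len(pool)))])
    return out


def _target_sentence(rng, spec, pools, framing, term_list, d_idx, articles):
    term = term_list[int(rng.integers(0, len(term_list)))]
    k = spec.window_words_per_side
    right = _draw_pool_words(rng, spec, pools, framing, d_idx, k)
    initial = rng.random() < spec.sentence_initial_rate
    tokens: list[str] = []
    if not initial:
        left = _draw_pool_words(rng, spec, pools, framing, d_idx, k)
        for w in left:
            if rng.random() < spec.article_rate:
                tokens.append(articles[int(rng.integers(0, len(articles)))])
            tokens.append(w)
    tokens.extend(term.split())
    for w in right:
        if rng.random() < spec.article_rate:
            tokens.append(articles[int(rng.integers(0, len(articles)))])
        tokens.append(w)
    return " ".join(tokens) + "."


def generate_lexicon(
    truth: GroundTruth, rater_noise_sd: float | None = None, seed: int | None = None
) -> ValenceLexicon:
    """Two-rater lexicon over every generated word.

    Rater 1 reports the true integer rating; rater 2 disagrees by one point
    on a fraction of words — the fraction a rounded Gaussian of the given
    sd would flip (P(|N(0, sd)| > 1/2) in each direction) — with the +1 and
    -1 discrepancies balanced within every true-rating level, so the merged
    lexicon is unbiased at each rating while interrater agreement stays
    realistic.  With sd 0 the raters are identical; the default sd of 0.35
    is calibrated so Cronbach's alpha over the generated lexicon sits at
    about 0.97, the high-agreement regime of careful human raters.
    Discrepancies are clipped to [1, 5].
    """
    from scipy.stats import norm

    sd = truth.rater_noise_sd if rater_noise_sd is None else rater_noise_sd
    if sd < 0:
        raise ConfigurationError("rater noise sd must be >= 0")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    flip = float(norm.cdf(-0.5, scale=sd)) if sd > 0 else 0.0
    # balance discrepancies within every word pool (framing x rating bin,
    # plus the filler vocabulary), so each pool's merged mean is exact
    pooled = {k: list(ws) for k, ws in sorted(truth.pools.items())}
    in_pool = {w for ws in pooled.values() for w in ws}
    filler = sorted(w for w in truth.word_ratings if w not in in_pool)
    if filler:
        pooled[("filler", truth.word_ratings[filler[0]])] = filler
    ratings = {}
    for (_, r), ws in pooled.items():
        k = int(round(flip * len(ws)))
        perm = rng.permutation(len(ws))
        delta = np.zeros(len(ws))
        delta[perm[:k]] = 1.0
        delta[perm[k : 2 * k]] = -1.0
        for w, d in zip(ws, delta):
            r1 = float(r)
            r2 = float(np.clip(r1 + d, 1, 5))
            ratings[w] = (r1, r2)
    return ValenceLexicon(ratings)


# ---------------------------------------------------------------------------
# Planted topic corpora
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopicCorpusSpec:
    """Planted-topic bag-of-words corpus for the topic-model stage."""

    n_topics: int = 2
    vocab_per_topic: int = 25
    n_docs: int = 60
    words_per_doc: int = 40
    mixture: tuple[float, ...] | None = None  # document-topic assignment probabilities
    overlap: float = 0.0  # fraction of each topic's vocabulary shared with the next
    positive_topics: tuple[int, ...] = ()  # topics whose words rate 4-5; others 1-2
    seed: int = 0


@dataclass(frozen=True)
class TopicGroundTruth:
    topic_words: tuple[tuple[str, ...], ...]
    assignments: tuple[int, ...]
    word_ratings: dict
    mixture: tuple[float, ...]
    seed: int


def generate_topic_corpus(spec: TopicCorpusSpec) -> tuple[list[Counter], TopicGroundTruth]:
    """Documents drawn from planted topic-word distributions.

    Each document is assigned one dominant planted topic (sampled from the
    mixture) and draws its words uniformly from that topic's vocabulary,
    with an ``overlap`` fraction of vocabulary shared between neighboring
    topics when configured.  Words carry true ratings: 4 or 5 for topics in
    ``positive_topics``, 1 or 2 otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    mixture = spec.mixture or tuple(1.0 / spec.n_topics for _ in range(spec.n_topics))
    if len(mixture) != spec.n_topics or not math.isclose(sum(mixture), 1.0, abs_tol=1e-9):
        raise ConfigurationError("mixture must be a probability vector over n_topics")
    n_shared = int(spec.overlap * spec.vocab_per_topic)
    vocabs: list[list[str]] = []
    for t in range(spec.n_topics):
        vocabs.append([f"t{t}w{i:03d}" for i in range(spec.vocab_per_topic)])
    if n_shared:
        for t in range(spec.n_topics - 1):
            vocabs[t + 1][:n_shared] = vocabs[t][-n_shared:]
    word_ratings = {}
    for t, vocab in enumerate(vocabs):
        hi = t in spec.positive_topics
        for w in vocab:
            if w not in word_ratings:
                word_ratings[w] = int(rng.integers(4, 6)) if hi else int(rng.integers(1, 3))
    docs: list[Counter] = []
    assignments: list[int] = []
    for _ in range(spec.n_docs):
        t = int(rng.choice(spec.n_topics, p=mixture))
        assignments.append(t)
        idx = rng.integers(0, len(vocabs[t]), size=spec.words_per_doc)
        docs.append(Counter(vocabs[t][i] for i in idx))
    truth = TopicGroundTruth(
        topic_words=tuple(tuple(v) for v in vocabs),
        assignments=tuple(assignments),
        word_ratings=word_ratings,
        mixture=tuple(mixture),
        seed=spec.seed,
    )
    return docs, truth


def small_recovery_spec(seed: int = 0, **overrides) -> SyntheticCorpusSpec:
    """A single-genre, reduced-volume spec for replicated recovery
    experiments (about 90k tokens per corpus); trajectories and window
    structure match the full-scale defaults."""
    base = dict(
        genres=("fiction",),
        docs_per_decade_per_genre=30,
        sentences_per_doc=8,
        filler_sentence_length=20,
        target_sentence_rate=0.25,
        words_per_pool=80,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticCorpusSpec(**base)
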