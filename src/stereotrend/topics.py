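"""Topic modeling of collocate bags and topic-valence classification.

Retained collocates are grouped into bag-of-words documents (by default one
document per synonym per decade, counts preserved) inside each stratum of
framing x century (optionally x genre).  Latent Dirichlet Allocation —
seeded variational inference via scikit-learn — yields per-topic word
distributions; each topic is labeled positive/neutral or negative by the
mean merged valence of its top words against a neutral threshold of 3.0
(strictly below the threshold is negative).  Positivity proportions per
framing x century feed the mixed ANOVA.

Century strata: decade bins 1800-1890 belong to the "1800s", 1900-1990 to
the "1900s"; 2000 and later bins are outside the two-century contrast and
are dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

from .collocation import CollocateRecord, TargetLexicon
from .errors import ComputationError, ConfigurationError
from .valence import ValenceLexicon

logger = logging.getLogger(__name__)

CENTURIES = ("1800s", "1900s")
POSITIVE_NEUTRAL = "positive_neutral"
NEGATIVE = "negative"


def century_of(decade: int) -> str | None:
    """Century label of a decade bin; None outside the 1800s/1900s contrast."""
    if 1800 <= decade <= 1890:
        return "1800s"
    if 1900 <= decade <= 1990:
        return "1900s"
    return None


@dataclass(frozen=True)
class TopicModelSpec:
    n_topics: int = 4
    doc_unit: str = "synonym_decade"  # or "synonym_decade_genre"
    topic_word_prior: float = 0.1
    doc_topic_prior: float = 1.0
    top_k: int = 10
    max_iter: int = 50
    seed: int = 0
    by_genre: bool = False
    neutral_threshold: float = 3.0

    def __post_init__(self):
        if self.n_topics < 2:
            raise ConfigurationError("n_topics must be >= 2")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")


@dataclass
class Topic:
    stratum: tuple  # (framing, century) or (framing, century, genre)
    topic_id: int
    words: tuple[str, ...]
    probabilities: np.ndarray  # aligned with words, sums to 1
    top_words: tuple[str, ...]
    seed: int
    mean_top_valence: float | None = None
    label: str | None = None


# ---------------------------------------------------------------------------
# Building topic documents
# ---------------------------------------------------------------------------


def build_topic_documents(
    records: Iterable[CollocateRecord],
    spec: TopicModelSpec,
    targets: "TargetLexicon",
) -> dict[tuple, list[Counter]]:
    """Collocate bags per stratum; one bag per synonym-decade (x genre).

    Counts are preserved as multiset multiplicity.  Decades outside the
    1800s/1900s centuries are dropped; strata with fewer documents than
    topics are flagged with a warning but still returned.
    """
    bags: dict[tuple, dict[tuple, Counter]] = {}
    for rec in records:
        century = century_of(rec.decade)
        if century is None:
            continue
        framing = targets.framing_of[rec.target]
        if spec.by_genre:
            stratum: tuple = (framing, century, rec.genre)
            doc_key: tuple = (rec.target, rec.decade, rec.genre)
        else:
            stratum = (framing, century)
            doc_key = (rec.target, rec.decade)
        bags.setdefault(stratum, {}).setdefault(doc_key, Counter())[rec.collocate] += rec.count
    out = {
        stratum: [docs[k] for k in sorted(docs)]
        for stratum, docs in sorted(bags.items())
    }
    for stratum, docs in out.items():
        if len(docs) < spec.n_topics:
            logger.warning("stratum %s has %d documents < %d topics", stratum, len(docs), spec.n_topics)
    return out


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


def fit_lda(bags: Sequence[Counter], spec: TopicModelSpec, stratum: tuple = ()) -> list[Topic]:
    """Seeded LDA on a list of bag-of-words documents.

    Returns one :class:`Topic` per component with its full word
    distribution (normalized to sum to 1) and its ``top_k`` highest
    probability words.  Reproducible: the same bags and seed give
    identical tables.
    """
    if not bags:
        raise ConfigurationError("fit_lda: no documents")
    vocab = sorted({w for bag in bags for w in bag})
    if len(vocab) < spec.n_topics:
        raise ConfigurationError(
            f"vocabulary size {len(vocab)} smaller than n_topics {spec.n_topics}"
        )
    index = {w: j for j, w in enumerate(vocab)}
    x = np.zeros((len(bags), len(vocab)), dtype=np.int64)
    for i, bag in enumerate(bags):
        for w, c in bag.items():
            x[i, index[w]] = c
    lda = LatentDirichletAllocation(
        n_components=spec.n_topics,
        doc_topic_prior=spec.doc_topic_prior,
        topic_word_prior=spec.topic_word_prior,
        max_iter=spec.max_iter,
        random_state=spec.seed,
    )
    lda.fit(x)
    dists = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    topics = []
    for k in range(spec.n_topics):
        order = np.argsort(-dists[k], kind="stable")
        top = tuple(vocab[j] for j in order[: spec.top_k])
        topics.append(
            Topic(
                stratum=stratum,
                topic_id=k,
                words=tuple(vocab),
                probabilities=dists[k],
                top_words=top,
                seed=spec.seed,
            )
        )
    return topics


def fit_lda_by_stratum(
    bags_by_stratum: dict[tuple, list[Counter]], spec: TopicModelSpec
) -> list[Topic]:
    topics: list[Topic] = []
    for stratum, bags in sorted(bags_by_stratum.items()):
        vocab_size = len({w for bag in bags for w in bag})
        if vocab_size < spec.n_topics:
            logger.warning("skipping stratum %s: vocabulary %d < n_topics %d",
                           stratum, vocab_size, spec.n_topics)
            continue
        topics.extend(fit_lda(bags, spec, stratum=stratum))
    return topics


# ---------------------------------------------------------------------------
# Topic-valence classification
# ---------------------------------------------------------------------------


def classify_topic_valence(
    topic: Topic, lexicon: ValenceLexicon, threshold: float = 3.0
) -> str:
    """Label a topic negative iff the mean merged valence of its top words
    is strictly below ``threshold`` (default 3.0, the neutral anchor).

    Unrated top words are dropped from the mean with a warning; a topic
    with no rated top words is unclassifiable.
    """
    rated = [lexicon.merged(w) for w in topic.top_words if w in lexicon]
    n_unrated = len(topic.top_words) - len(rated)
    if n_unrated:
        logger.warning("topic %s/%d: %d unrated top word(s) dropped",
                       topic.stratum, topic.topic_id, n_unrated)
    if not rated:
        raise ComputationError(
            f"topic {topic.stratum}/{topic.topic_id} has no rated top words"
        )
    mean = float(np.mean(rated))
    topic.mean_top_valence = mean
    topic.label = NEGATIVE if mean < threshold else POSITIVE_NEUTRAL
    return topic.label


@dataclass(frozen=True)
class TopicValenceSummary:
    """Positivity proportions per framing x century (long format)."""

    frame: pd.DataFrame  # columns framing, century, n_topics, n_positive_neutral, proportion_positive_neutral

    def proportion(self, framing: str, century: str) -> float:
        sub = self.frame[(self.frame["framing"] == framing) & (self.frame["century"] == century)]
        return float(sub["proportion_positive_neutral"].iloc[0])


def positivity_proportions(topics: Iterable[Topic]) -> TopicValenceSummary:
    """Count positive/neutral topics per framing x century (genres pooled)."""
    tally: dict[tuple[str, str], list[int]] = {}
    for t in topics:
        if t.label is None:
            raise ComputationError("positivity_proportions: classify topics first")
        framing, century = t.stratum[0], t.stratum[1]
        cell = tally.setdefault((framing, century), [0, 0])
        cell[0] += 1
        cell[1] += int(t.label == POSITIVE_NEUTRAL)
    rows = [
        {
            "framing": framing,
            "century": century,
            "n_topics": n,
            "n_positive_neutral": npos,
            "proportion_positive_neutral": npos / n,
        }
        for (framing, century), (n, npos) in sorted(tally.items())
    ]
    return TopicValenceSummary(pd.DataFrame(rows))


def topics_to_frame(topics: Iterable[Topic]) -> pd.DataFrame:
    """Long CSV layout: framing, century, genre, topic_id, rank, word, probability."""
    rows = []
    for t in topics:
        framing, century = t.stratum[0], t.stratum[1]
        genre = t.stratum[2] if len(t.stratum) > 2 else ""
        order = np.argsort(-t.probabilities, kind="stable")
        for rank, j in enumerate(order[: len(t.top_words)], 1):
            rows.append(
                {
                    "framing": framing,
                    "century": century,
                    "genre": genre,
                    "topic_id": t.topic_id,
                    "rank": rank,
                    "word": t.words[j],
                    "probability": float(t.probabilities[j]),
                }
            )
    return pd.DataFrame(rows)


def labels_to_frame(topics: Iterable[Topic]) -> pd.DataFrame:
    rows = []
    for t in topics:
        framing, century = t.stratum[0], t.stratum[1]
        genre = t.stratum[2] if len(t.stratum) > 2 else ""
        rows.append(
            {
                "framing": framing,
                "century": century,
                "genre": genre,
                "topic_id": t.topic_id,
                "mean_top_valence": t.mean_top_valence,
                "label": t.label,
                "seed": t.seed,
            }
        )
    return pd.DataFrame(rows)
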