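"""Valence scoring of collocates and the cumulative narrative score.

Each retained collocate carries two human ratings on a 1 (very negative) to
5 (very positive) stereotype-valence scale; the two raters are merged by
simple mean.  Interrater reliability is quantified with Cronbach's alpha
(raters as items) and a Feldt 95% confidence interval.

Per synonym and decade, retained collocates are aggregated into a mean
valence (count-weighted by default), and synonym means are combined —
weighted by how often the synonym appeared in that decade — into the
cumulative narrative score (CANS) per framing per decade.  The CANS is a
convex combination of synonym means, so it always stays within [1, 5].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .collocation import CollocateRecord, TargetLexicon
from .errors import ComputationError, DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Valence lexicon
# ---------------------------------------------------------------------------


def _check_rating(word: str, r: float) -> float:
    r = float(r)
    if not (1.0 <= r <= 5.0):
        raise DataError(f"rating {r} for {word!r} outside [1, 5]")
    if (2 * r) != int(2 * r):
        raise DataError(f"rating {r} for {word!r} is not an integer or half-integer")
    return r


@dataclass(frozen=True)
class ValenceLexicon:
    """word -> (rater1, rater2) stereotype-valence ratings on the 1-5 scale."""

    ratings: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for word, (r1, r2) in self.ratings.items():
            _check_rating(word, r1)
            _check_rating(word, r2)
            if abs(r1 - r2) > 2:
                logger.warning("raters diverge by > 2 points on %r: %s vs %s", word, r1, r2)

    def __contains__(self, word: str) -> bool:
        return word in self.ratings

    def __len__(self) -> int:
        return len(self.ratings)

    def merged(self, word: str) -> float:
        r1, r2 = self.ratings[word]
        return (r1 + r2) / 2.0

    def rating_matrix(self) -> np.ndarray:
        """n_words x 2 array of ratings, word order sorted."""
        return np.array([self.ratings[w] for w in sorted(self.ratings)], dtype=float)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ValenceLexicon":
        ratings: dict[str, tuple[float, float]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("word\t"):
                    continue
                word, r1, r2 = line.split("\t")
                ratings[word.lower()] = (float(r1), float(r2))
        return cls(ratings)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\trater1\trater2\n")
            for word in sorted(self.ratings):
                r1, r2 = self.ratings[word]
                fh.write(f"{word}\t{r1:g}\t{r2:g}\n")


# ---------------------------------------------------------------------------
# Interrater reliability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    ci_low: float
    ci_high: float
    n_items: int
    k_raters: int


def cronbach_alpha(ratings: np.ndarray, confidence: float = 0.95) -> ReliabilityResult:
    """Cronbach's alpha over an n_items x k_raters table, with Feldt CI.

    alpha = k/(k-1) * (1 - sum_i var_i / var_total), sample variances over
    items (rows).  The Feldt interval uses F quantiles with degrees of
    freedom (n-1, (n-1)(k-1)).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise DataError("cronbach_alpha needs an n_items x k_raters table with n >= 3, k >= 2")
    n, k = x.shape
    var_cols = x.var(axis=0, ddof=1)
    var_total = x.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ComputationError("cronbach_alpha undefined: zero total-score variance")
    alpha = k / (k - 1) * (1 - var_cols.sum() / var_total)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    c = 1 - confidence
    lo = 1 - (1 - alpha) * sps.f.isf(c / 2, df1, df2)
    hi = 1 - (1 - alpha) * sps.f.ppf(c / 2, df1, df2)
    return ReliabilityResult(alpha=float(alpha), ci_low=float(lo), ci_high=float(hi),
                             n_items=n, k_raters=k)


# ---------------------------------------------------------------------------
# Synonym-decade means and the narrative score
# ---------------------------------------------------------------------------


def synonym_decade_means(
    records: Iterable[CollocateRecord],
    lexicon: ValenceLexicon,
    weighted: bool = True,
    missing: str = "error",
) -> pd.DataFrame:
    """Mean merged valence of each synonym's retained collocates per decade.

    ``weighted=True`` weights each collocate by its co-occurrence count.
    Unrated collocates are a hard error by default (``missing="error"``) or
    dropped with a warning (``missing="skip"``).

    Returns columns [synonym, decade, mean_valence, n_collocates, total_count].
    """
    if missing not in ("error", "skip"):
        raise DataError(f"unknown missing-rating policy {missing!r}")
    unrated: set[str] = set()
    acc: dict[tuple[str, int], list[tuple[float, int]]] = {}
    for rec in records:
        if rec.collocate not in lexicon:
            unrated.add(rec.collocate)
            continue
        acc.setdefault((rec.target, rec.decade), []).append(
            (lexicon.merged(rec.collocate), rec.count)
        )
    if unrated:
        if missing == "error":
            raise DataError(
                "unrated collocates (add ratings or use missing='skip'): "
                + ", ".join(sorted(unrated)[:20])
                + ("..." if len(unrated) > 20 else "")
            )
        logger.warning("dropping %d unrated collocate(s)", len(unrated))
    rows = []
    for (syn, decade), pairs in sorted(acc.items()):
        ratings = np.array([p[0] for p in pairs])
        counts = np.array([p[1] for p in pairs], dtype=float)
        w = counts if weighted else np.ones_like(counts)
        rows.append(
            {
                "synonym": syn,
                "decade": decade,
                "mean_valence": float(np.average(ratings, weights=w)),
                "n_collocates": len(pairs),
                "total_count": int(counts.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["synonym", "decade", "mean_valence", "n_collocates", "total_count"])


@dataclass(frozen=True)
class NarrativeScoreSeries:
    """Per-framing, per-decade cumulative narrative score (CANS).

    ``frame`` has columns [framing, decade, cans, n_synonyms, total_freq],
    sorted by framing then decade; decades with no data are absent.
    """

    frame: pd.DataFrame

    def series(self, framing: str) -> pd.Series:
        sub = self.frame[self.frame["framing"] == framing]
        return pd.Series(sub["cans"].to_numpy(), index=sub["decade"].to_numpy(), name=framing)

    def framings(self) -> list[str]:
        return sorted(self.frame["framing"].unique())

    def to_csv(self, path: str | Path, metadata: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if metadata:
                fh.write(f"# {metadata}\n")
            self.frame.to_csv(fh, index=False)


def cumulative_narrative_score(
    means: pd.DataFrame,
    synonym_freqs: Mapping[tuple[str, int], int],
    targets: TargetLexicon,
) -> NarrativeScoreSeries:
    """Frequency-weighted combination of synonym means into the CANS.

    CANS(framing, decade) = sum_s freq_s * mean_s / sum_s freq_s over that
    framing's synonyms with a defined mean in the decade, where freq_s is
    the number of times the synonym appeared in the decade.
    """
    rows = []
    seen_framings: set[str] = set()
    for (framing, decade), grp in means.assign(
        framing=means["synonym"].map(targets.framing_of)
    ).groupby(["framing", "decade"]):
        seen_framings.add(framing)
        freqs = np.array(
            [synonym_freqs.get((syn, decade), 0) for syn in grp["synonym"]], dtype=float
        )
        if freqs.sum() <= 0:
            logger.warning("no synonym frequencies for %s in %s; decade skipped", framing, decade)
            continue
        cans = float(np.average(grp["mean_valence"].to_numpy(), weights=freqs))
        rows.append(
            {
                "framing": framing,
                "decade": int(decade),
                "cans": cans,
                "n_synonyms": len(grp),
                "total_freq": int(freqs.sum()),
            }
        )
    for framing in targets.framings():
        if framing not in seen_framings:
            raise DataError(f"framing {framing!r} has no scored synonyms anywhere")
    frame = pd.DataFrame(rows, columns=["framing", "decade", "cans", "n_synonyms", "total_freq"])
    frame = frame.sort_values(["framing", "decade"]).reset_index(drop=True)
    return NarrativeScoreSeries(frame)
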