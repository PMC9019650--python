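import numpy as np
import pytest

from stereotrend import (
    ComputationError,
    DataError,
    TargetLexicon,
    ValenceLexicon,
    cronbach_alpha,
    cumulative_narrative_score,
    synonym_decade_means,
)
from stereotrend.collocation import CollocateRecord

from oracles import alpha_direct


def rec(target, collocate, decade, count, mi=5.0):
    return CollocateRecord(target=target, collocate=collocate, decade=decade, genre=None,
                           count=count, target_freq=10, collocate_freq=10,
                           stratum_n=10000, mi=mi)


class TestLexicon:
    def test_ratings_validated(self):
        with pytest.raises(DataError):
            ValenceLexicon({"w": (0.0, 3.0)})
        with pytest.raises(DataError):
            ValenceLexicon({"w": (3.3, 3.0)})

    def test_half_integers_accepted_and_merged(self):
        lex = ValenceLexicon({"w": (2.5, 4.0)})
        assert lex.merged("w") == 3.25

    def test_tsv_round_trip(self, tmp_path):
        lex = ValenceLexicon({"frail": (1.0, 2.0), "wise": (5.0, 4.5)})
        p = tmp_path / "lex.tsv"
        lex.to_tsv(p)
        assert ValenceLexicon.from_tsv(p).ratings == lex.ratings


class TestCronbachAlpha:
    def test_identical_raters_alpha_one(self):
        x = np.column_stack([np.arange(1, 6), np.arange(1, 6)])
        assert cronbach_alpha(x).alpha == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        x = np.column_stack([[1, 2, 3, 4, 5], [2, 3, 4, 5, 5]])
        res = cronbach_alpha(x)
        assert res.alpha == pytest.approx(8 / 8.2, abs=1e-12)  # 0.97561
        assert res.ci_low <= res.alpha <= res.ci_high

    def test_matches_direct_formula(self, rng):
        x = rng.integers(1, 6, size=(40, 2)).astype(float)
        x[:, 1] = np.clip(x[:, 0] + rng.integers(-1, 2, size=40), 1, 5)
        assert cronbach_alpha(x).alpha == pytest.approx(alpha_direct(x), abs=1e-12)

    def test_independent_raters_near_zero(self, rng):
        x = rng.normal(size=(5000, 2))
        assert abs(cronbach_alpha(x).alpha) < 0.1

    def test_shift_invariance(self, rng):
        x = rng.normal(size=(30, 2))
        shifted = x.copy()
        shifted[:, 1] += 1.7
        assert cronbach_alpha(shifted).alpha == pytest.approx(cronbach_alpha(x).alpha, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(ComputationError):
            cronbach_alpha(np.full((5, 2), 3.0))

    def test_matches_pingouin_including_feldt_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.integers(1, 6, size=(60, 2)).astype(float)
        x[:, 1] = np.clip(x[:, 0] + rng.normal(0, 0.6, 60).round(), 1, 5)
        res = cronbach_alpha(x)
        a, ci = pg.cronbach_alpha(data=pd.DataFrame(x))
        assert res.alpha == pytest.approx(a, abs=1e-10)
        assert res.ci_low == pytest.approx(ci[0], abs=5e-4)
        assert res.ci_high == pytest.approx(ci[1], abs=5e-4)


class TestSynonymMeans:
    def test_single_collocate_any_count(self):
        lex = ValenceLexicon({"kind": (3.0, 4.0)})
        means = synonym_decade_means([rec("elderly", "kind", 1850, 7)], lex)
        assert means["mean_valence"].tolist() == [3.5]

    def test_count_weighted_mean(self):
        lex = ValenceLexicon({"lo": (2.0, 2.0), "hi": (4.0, 4.0)})
        means = synonym_decade_means(
            [rec("elderly", "lo", 1850, 1), rec("elderly", "hi", 1850, 3)], lex
        )
        assert means["mean_valence"].iloc[0] == pytest.approx(3.5)

    def test_unweighted_mode(self):
        lex = ValenceLexicon({"lo": (2.0, 2.0), "hi": (4.0, 4.0)})
        means = synonym_decade_means(
            [rec("elderly", "lo", 1850, 1), rec("elderly", "hi", 1850, 3)], lex, weighted=False
        )
        assert means["mean_valence"].iloc[0] == pytest.approx(3.0)

    def test_neutral_corpus_is_exactly_three(self):
        lex = ValenceLexicon({w: (3.0, 3.0) for w in "abc"})
        means = synonym_decade_means(
            [rec("elderly", w, 1850, c) for w, c in zip("abc", (1, 5, 9))], lex
        )
        assert means["mean_valence"].iloc[0] == 3.0

    def test_unrated_collocate_is_hard_error_by_default(self):
        lex = ValenceLexicon({"kind": (3.0, 3.0)})
        with pytest.raises(DataError, match="mystery"):
            synonym_decade_means([rec("elderly", "mystery", 1850, 1)], lex)

    def test_unrated_skip_policy(self):
        lex = ValenceLexicon({"kind": (4.0, 4.0)})
        means = synonym_decade_means(
            [rec("elderly", "mystery", 1850, 9), rec("elderly", "kind", 1850, 1)],
            lex, missing="skip",
        )
        assert means["mean_valence"].tolist() == [4.0]


class TestNarrativeScore:
    @pytest.fixture
    def targets(self):
        return TargetLexicon.from_pairs(age_terms=("elderly", "aged"), role_terms=("grandma",))

    def _means(self, lex, records):
        return synonym_decade_means(records, lex)

    def test_single_synonym_equals_its_mean(self, targets):
        lex = ValenceLexicon({"kind": (4.0, 4.0), "g": (3.0, 3.0)})
        means = self._means(lex, [rec("elderly", "kind", 1850, 2), rec("grandma", "g", 1850, 1)])
        scores = cumulative_narrative_score(means, {("elderly", 1850): 5, ("grandma", 1850): 3}, targets)
        assert scores.series("age_based")[1850] == 4.0

    def test_frequency_weighted_combination(self, targets):
        lex = ValenceLexicon({"lo": (2.0, 2.0), "hi": (4.0, 4.0), "g": (3.0, 3.0)})
        means = self._means(
            lex,
            [rec("elderly", "lo", 1850, 1), rec("aged", "hi", 1850, 1), rec("grandma", "g", 1850, 1)],
        )
        scores = cumulative_narrative_score(
            means, {("elderly", 1850): 1, ("aged", 1850): 3, ("grandma", 1850): 1}, targets
        )
        assert scores.series("age_based")[1850] == pytest.approx(3.5)

    def test_equal_means_invariant_to_weights(self, targets, rng):
        lex = ValenceLexicon({"m": (3.5, 3.5), "g": (3.5, 3.5)})
        means = self._means(lex, [rec("elderly", "m", 1850, 2), rec("aged", "m", 1850, 9),
                                  rec("grandma", "g", 1850, 4)])
        freqs = {("elderly", 1850): int(rng.integers(1, 99)),
                 ("aged", 1850): int(rng.integers(1, 99)), ("grandma", 1850): 7}
        scores = cumulative_narrative_score(means, freqs, targets)
        assert scores.series("age_based")[1850] == pytest.approx(3.5)

    def test_weight_scaling_invariance(self, targets):
        lex = ValenceLexicon({"lo": (2.0, 2.0), "hi": (4.0, 4.0), "g": (3.0, 3.0)})
        means = self._means(
            lex,
            [rec("elderly", "lo", 1850, 1), rec("aged", "hi", 1850, 1), rec("grandma", "g", 1850, 1)],
        )
        f1 = {("elderly", 1850): 1, ("aged", 1850): 3, ("grandma", 1850): 1}
        f2 = {k: 10 * v for k, v in f1.items()}
        s1 = cumulative_narrative_score(means, f1, targets)
        s2 = cumulative_narrative_score(means, f2, targets)
        assert s1.series("age_based")[1850] == pytest.approx(s2.series("age_based")[1850])

    def test_convex_combination_bounds(self, targets, rng):
        words = {f"w{i}": (float(rng.integers(1, 6)), float(rng.integers(1, 6))) for i in range(20)}
        words["g"] = (3.0, 3.0)
        lex = ValenceLexicon(words)
        records = [rec("elderly", f"w{i}", 1850, int(rng.integers(1, 9))) for i in range(10)]
        records += [rec("aged", f"w{i}", 1850, int(rng.integers(1, 9))) for i in range(10, 20)]
        records.append(rec("grandma", "g", 1850, 1))
        means = self._means(lex, records)
        scores = cumulative_narrative_score(
            means, {("elderly", 1850): 4, ("aged", 1850): 9, ("grandma", 1850): 1}, targets
        )
        cans = scores.series("age_based")[1850]
        syn_means = means[means.synonym.isin(["elderly", "aged"])]["mean_valence"]
        assert syn_means.min() - 1e-12 <= cans <= syn_means.max() + 1e-12
        assert 1.0 <= cans <= 5.0

    def test_framing_without_synonyms_errors(self, targets):
        lex = ValenceLexicon({"kind": (4.0, 4.0)})
        means = self._means(lex, [rec("elderly", "kind", 1850, 2)])
        with pytest.raises(DataError, match="role_based"):
            cumulative_narrative_score(means, {("elderly", 1850): 5}, targets)

    def test_decades_without_data_absent(self, targets):
        lex = ValenceLexicon({"kind": (4.0, 4.0), "g": (3.0, 3.0)})
        means = self._means(lex, [rec("elderly", "kind", 1850, 2), rec("grandma", "g", 1870, 1)])
        scores = cumulative_narrative_score(
            means, {("elderly", 1850): 5, ("grandma", 1870): 2}, targets
        )
        assert scores.series("age_based").index.tolist() == [1850]
        assert scores.series("role_based").index.tolist() == [1870]
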