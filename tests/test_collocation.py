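import math

import pytest

from stereotrend import (
    ConfigurationError,
    DataError,
    Document,
    TargetLexicon,
    WindowConfig,
    compute_mi,
    count_collocates,
    extract_window,
    filter_collocates,
    find_target_occurrences,
    tokenize_and_segment,
)
from stereotrend.collocation import CollocateRecord, build_collocate_records
from stereotrend.corpus import corpus_frequencies

from oracles import brute_collocate_counts


def tok(text, year=1900, genre="fiction"):
    return tokenize_and_segment(Document("t", year, genre, text))


def rec(mi, count=5, collocate="kind", target="elderly"):
    return CollocateRecord(target=target, collocate=collocate, decade=1900, genre=None,
                           count=count, target_freq=10, collocate_freq=10,
                           stratum_n=10000, mi=mi)


class TestOccurrences:
    def test_longest_match_wins(self, targets):
        doc = tok("the senior citizen spoke.")
        occs = find_target_occurrences(doc, targets)
        assert [(o.term, o.tok_idx) for o in occs] == [("senior citizen", 1)]

    def test_no_targets_empty(self, targets):
        assert find_target_occurrences(tok("nothing to see here."), targets) == []

    def test_sentence_initial_flag(self, targets):
        doc = tok("Old people vote. Some old people stay home.")
        occs = find_target_occurrences(doc, targets)
        assert [(o.sent_idx, o.tok_idx, o.sentence_initial) for o in occs] == [
            (0, 0, True),
            (1, 1, False),
        ]

    def test_positions_consumed_once(self, targets):
        # "senior citizen" consumes "citizen": no second occurrence
        lex = TargetLexicon.from_pairs(age_terms=("senior citizen", "citizen"))
        occs = find_target_occurrences(tok("one senior citizen here."), lex)
        assert [o.term for o in occs] == ["senior citizen"]

    def test_empty_lexicon_is_error(self, targets):
        with pytest.raises(ConfigurationError):
            find_target_occurrences(tok("x."), TargetLexicon({}))


class TestWindow:
    def test_articles_skipped_not_counted(self, targets):
        doc = tok("the kind elderly man.")
        (occ,) = find_target_occurrences(doc, targets)
        assert sorted(extract_window(doc, occ, WindowConfig())) == ["kind", "man"]

    def test_span_boundary_exact(self, targets):
        doc = tok("elderly w1 w2 w3 w4 w5 w6 w7.")
        (occ,) = find_target_occurrences(doc, targets)
        window = extract_window(doc, occ, WindowConfig(span=6))
        assert window == ["w1", "w2", "w3", "w4", "w5", "w6"]

    def test_sentence_initial_excludes_previous_sentence(self, targets):
        doc = tok("Before words here. Elderly folk arrived.")
        occs = find_target_occurrences(doc, targets)
        occ = [o for o in occs if o.sentence_initial][0]
        window = extract_window(doc, occ, WindowConfig())
        assert window == ["folk", "arrived"]

    def test_window_crosses_sentences_otherwise(self, targets):
        doc = tok("Last words. The elderly left.")
        (occ,) = find_target_occurrences(doc, targets)
        assert sorted(extract_window(doc, occ, WindowConfig(span=2))) == [
            "last", "left", "words",
        ]

    def test_within_sentence_mode(self, targets):
        doc = tok("Last words. The elderly left.")
        (occ,) = find_target_occurrences(doc, targets)
        cfg = WindowConfig(span=2, cross_sentence="within_sentence")
        assert extract_window(doc, occ, cfg) == ["left"]

    def test_multiword_target_tokens_not_collocates(self, targets):
        doc = tok("kind old people smiled.")
        (occ,) = find_target_occurrences(doc, targets)
        window = extract_window(doc, occ, WindowConfig())
        assert "old" not in window and "people" not in window
        assert sorted(window) == ["kind", "smiled"]

    @pytest.mark.parametrize("n_articles", [0, 1, 3, 5])
    def test_article_invariance(self, targets, n_articles):
        pad = ("the a an " * n_articles).strip()
        text = f"far w1 w2 w3 w4 w5 {pad} elderly.".replace("  ", " ")
        doc = tok(text)
        (occ,) = find_target_occurrences(doc, targets)
        window = extract_window(doc, occ, WindowConfig(span=6))
        assert "far" in window  # articles never push content words out


class TestCounting:
    def test_counts_are_additive_within_window(self, targets):
        doc = tok("frail frail elderly rest. frail elderly next.")
        cfg = WindowConfig(cross_sentence="within_sentence")
        table = count_collocates([doc], targets, cfg)
        # first window holds "frail" twice, second once
        assert table.counts[("elderly", "frail", 1900)] == 3

    def test_strata_disjoint(self, targets):
        d1 = tok("kind elderly one.", year=1850)
        d2 = tok("kind elderly two.", year=1950)
        table = count_collocates([d1, d2], targets, WindowConfig())
        assert table.counts[("elderly", "kind", 1850)] == 1
        assert table.counts[("elderly", "kind", 1950)] == 1

    def test_matches_brute_force_on_random_corpus(self, rng, random_corpus, targets):
        cfg = WindowConfig(span=4)
        table = count_collocates(random_corpus, targets, cfg, by_genre=True)
        term_tokens = {t: tuple(t.split()) for t in targets.terms}
        brute_counts, brute_tf = brute_collocate_counts(
            [(d.sentences, (d.decade, d.genre)) for d in random_corpus],
            term_tokens, cfg.span, cfg.excluded_articles, by_key=True,
        )
        assert table.counts == brute_counts
        assert table.target_freqs == brute_tf


class TestMI:
    def test_independence_point_is_zero(self):
        # cooc = tf * cf * W / N exactly
        assert compute_mi(24, 10, 20, 100, span=6) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        assert compute_mi(8, 10, 20, 10000, 6) == pytest.approx(
            math.log2(8 * 10000 / (10 * 20 * 12)), abs=1e-12
        )
        assert compute_mi(8, 10, 20, 10000, 6) == pytest.approx(5.0589, abs=5e-5)

    def test_doubling_n_adds_one_bit(self):
        a = compute_mi(5, 7, 11, 5000, 6)
        b = compute_mi(5, 7, 11, 10000, 6)
        assert b - a == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_cooccurrence(self):
        vals = [compute_mi(c, 10, 20, 10000, 6) for c in range(1, 12)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_zero_counts_are_domain_error(self):
        with pytest.raises(DataError):
            compute_mi(0, 10, 20, 10000, 6)


class TestFilter:
    def test_threshold_inclusive(self):
        cfg = WindowConfig(mi_threshold=3.0)
        assert filter_collocates([rec(3.0)], cfg) == [rec(3.0)]

    def test_just_below_threshold_dropped(self):
        assert filter_collocates([rec(2.999)], WindowConfig()) == []

    def test_exclusion_list_beats_high_mi(self):
        cfg = WindowConfig()
        assert filter_collocates([rec(8.0)], cfg, exclusion={"kind"}) == []
        assert filter_collocates([rec(8.0)], cfg, exclusion={"elderly": {"kind"}}) == []
        assert filter_collocates([rec(8.0)], cfg, exclusion={"other": {"kind"}}) == [rec(8.0)]

    def test_min_cooccurrence(self):
        cfg = WindowConfig(min_cooccurrence=3)
        assert filter_collocates([rec(5.0, count=2)], cfg) == []
        assert filter_collocates([rec(5.0, count=3)], cfg) == [rec(5.0, count=3)]

    def test_idempotent(self, rng):
        recs = [rec(float(m), count=int(c)) for m, c in
                zip(rng.normal(3, 2, 50), rng.integers(1, 9, 50))]
        cfg = WindowConfig()
        once = filter_collocates(recs, cfg)
        assert filter_collocates(once, cfg) == once


def test_records_carry_consistent_mi(random_corpus, targets):
    cfg = WindowConfig()
    stats = corpus_frequencies(random_corpus)
    table = count_collocates(random_corpus, targets, cfg)
    for r in build_collocate_records(table, stats, cfg):
        assert r.mi == pytest.approx(
            math.log2(r.count * r.stratum_n / (r.target_freq * r.collocate_freq * 12)), abs=1e-12
        )
        assert r.count >= 1
        assert r.count <= r.target_freq * 12  # at most 2*span tokens per occurrence
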