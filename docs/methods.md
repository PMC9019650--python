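# Methods

## The measurement model

The package operationalizes stereotype drift as a change in the valence of
the lexical company a target term keeps. A *target* (node) term is an
age-based or role-based reference to an older adult; its *collocates* are
the content words inside a symmetric window around each occurrence. The
assumption carried through every stage is a priming one: repeated
co-occurrence of a word with a target transfers that word's affective
tone to the concept, so the frequency-weighted mean valence of retained
collocates tracks the narrative around the target population.

### Window rules

The window spans six content tokens on each side of the node. Three rules
matter, and all three are exercised by dedicated tests and a brute-force
oracle:

- articles (default `{a, an, the}`, configurable) are skipped entirely:
  they are never collocates and never consume span budget, so inserting any
  number of articles between node and collocate cannot push the collocate
  out of the window;
- windows may cross sentence boundaries, **except** that a node which is
  the first word of its sentence takes nothing from the preceding sentence
  (a strict within-sentence mode is available via
  `WindowConfig(cross_sentence="within_sentence")`);
- the node's own tokens are never its collocates; overlapping multiword
  nodes resolve longest-match first, left to right, and every token
  position feeds at most one occurrence.

Tokenization is deliberately minimal and deterministic: whitespace split,
lowercase, edge punctuation stripped, sentence breaks at terminal
`. ! ?` guarded by a small abbreviation list. Collocates are surface
forms; no lemmatization or POS tagging is attempted. These are explicit
substitutes for unspecified preprocessing, not reconstructions of any
particular toolchain, and they are what the brute-force oracle re-implements
literally.

### Mutual Information and filtering

For co-occurrence count `f(n,c)`, marginal frequencies `f(n)`, `f(c)`, and
stratum token total `N`,

    MI = log2( f(n,c) · N / ( f(n) · f(c) · W ) ),  W = 2 · span,

the window-size-corrected pointwise MI used by the large structured English
corpora. Retention requires `MI ≥ 3` (inclusive — the boundary case is
tested), a minimum co-occurrence count (default 1), and absence from an
optional exclusion list that substitutes for a human relevance check.
Marginals and `N` are computed per decade by default (genres pooled); a
decade × genre stratification is available for the topic stage. `f(n)` for
a multiword node is its matched-occurrence count, which coincides with
corpus frequency for single words and is the natural generalization —
a unigram marginal table has no entry for *senior citizen*.

### Valence and the narrative score

Ratings are 1–5 (integers or halves) from two raters, merged by simple
mean; divergences above two points are logged for audit. Interrater
reliability is Cronbach's α with raters as items and the Feldt F-based 95%
interval on `(n−1, (n−1)(k−1))` degrees of freedom (the CI method is a
package choice; it matches pingouin's to numerical precision and is
cross-checked against it in the tests).

Per synonym and decade, retained collocates are averaged with
co-occurrence-count weights (an unweighted mode exists; count-weighting
follows the priming rationale of repeated association). Synonym means are
then combined into the cumulative narrative score

    CANS(framing, decade) = Σ_s f_s · mean_s / Σ_s f_s,

with `f_s` the synonym's occurrence count that decade. The CANS is a convex
combination, hence always inside `[1, 5]` and invariant to rescaling all
weights; decades with no scored synonym are absent, never zero-filled.
Unrated collocates are a hard error by default (`missing="skip"` drops them
with a warning) so silent coverage gaps cannot bias a series.

## Trend comparison

CANS is regressed on the decade index (1810 → 0, so the intercept is the
1810 score). Percent decline over `D` decades is
`100 · (−β) · (D−1) / intercept`: `D` decades span `D−1` decade-long
intervals, the reading under which the standard summary arithmetic of this
literature is self-consistent, and the one the package tests pin down
(3.13 intercept with β = −0.0067 gives 4.28% over 21 decades; 3.04 with
β = −0.023 gives 15.13%).

The slope difference between framings is the interaction test in the pooled
homoscedastic regression `y ~ 1 + g + t + g·t`; `F = t²` of the interaction
coefficient on `(1, N − 4)` degrees of freedom — `(1, 38)` for two 21-point
series. No autocorrelation-robust errors, changepoints, or nonlinear trends
are offered: the estimand is a straight-line contrast.

## Topic stage

Retained collocates form one bag-of-words document per synonym-decade
(optionally per genre) inside each framing × century stratum; counts are
preserved as multiset multiplicity. Decades 1800–1890 are the "1800s",
1900–1990 the "1900s"; 2000+ bins fall outside the two-century contrast and
are dropped. LDA runs per stratum via scikit-learn's seeded variational
inference with symmetric priors (topic–word 0.1, document–topic 1.0),
default 4 topics per stratum and top-10 words per topic — the topic count,
priors, and document unit are genuinely open design choices, all exposed in
`TopicModelSpec`, and the same seed always reproduces the same tables.

A topic is *negative* iff the mean merged valence of its rated top words is
strictly below 3.0 (the neutral anchor); ties at exactly 3.0 are
positive/neutral. Raising any top word's rating can therefore never flip a
topic to negative (tested as a monotonicity property). Positivity
proportions per framing × century feed the ANOVA.

## Mixed ANOVA

One between-units factor (framing) and one within-units factor (century),
complete cases only. With two within levels the decomposition is computed
exactly through unit sums and differences: sums carry the between effect
(one-way ANOVA, error = units within groups), differences carry the within
main effect (Type III: the *unweighted* mean of group mean-differences
tested against zero) and the interaction (group effect on differences,
error = within × units within groups). This reduces to the classical
balanced split-plot formulas, handles unbalanced groups with
Type III-equivalent tests, and gives `(1, N−2)` degrees of freedom for every
effect in a 2 × 2 design — `(1, 37)` at 39 units. For more than two within
levels a regression-based Type III decomposition (statsmodels, Sum
contrasts) is used. Effect sizes are partial η² = SS_effect / (SS_effect +
SS_error-of-that-stratum). Binary (0/1) positivity responses are analyzed
with the same decomposition, mirroring ANOVA-on-proportions practice; no
sphericity correction is needed with two within levels, and none is offered.

The repeated-measures *unit* in the packaged H2 pipeline is a topic slot —
(framing, genre, topic id) paired across the two centuries. That pairing is
a package convention: nothing in the published design pins down what entity
carries the repeated measure, so `two_way_mixed_anova` accepts any
long-format table and the pipeline documents its own choice rather than
presenting it as canonical.

## Synthetic data: what it emulates and what it does not

`generate_corpus` plants the statistical structure the pipeline measures:

- 21 decade bins (1810–2010), four genre labels, documents of short
  synthetic sentences;
- each target sentence embeds one target term with exactly six pool words
  per side (none on the left for the ~10% of targets placed
  sentence-initially, exercising that rule), with articles interleaved at
  rate 0.25 to exercise the span rule;
- pool words are framing-specific and stratified by integer rating 1–5;
  the per-decade mean rating follows the planted linear trajectory by
  mixing the two adjacent rating bins, so the expected in-window valence is
  exact at every decade. Default trajectories are the published regime:
  age-based 3.04 − 0.023·t, role-based 3.13 − 0.0067·t;
- filler sentences use a disjoint vocabulary, so collocate marginals come
  entirely from windows.

Two scale presets are provided and used as-is by the tests and the
acceptance script: the full-scale default (2,016 documents, ≈400k tokens)
and a single-genre reduced preset (`small_recovery_spec`, 630 documents,
≈95k tokens per corpus) for experiments replicated over many seeds. Both
satisfy the generator's design constraint that expected MI at co-occurrence
count 1 clears the MI ≥ 3 threshold with margin (`N` per decade well above
`8 · W · f(node) · f(collocate)`), so the MI filter retains essentially all
pool words (~98%) and cannot select collocates by frequency — without that
constraint the filter would prune rare-bin words differentially and distort
the recovered trajectory.

The two-rater lexicon reports the true rating as rater 1; rater 2 disagrees
by ±1 on the fraction of words a rounded Gaussian of sd 0.35 would flip,
with the +1/−1 discrepancies balanced *within each word pool* so the merged
lexicon is unbiased at every rating level. The sd default is calibrated in
closed form so α over the generated lexicon is ≈0.97, the agreement regime
of careful human raters. The balancing is deliberate: an unbalanced rater
would shift whole pools by a decade-constant offset, which moves intercepts
(and, through drifting bin mixtures, slopes) by an amount the per-series OLS
interval cannot see. With it, the full pipeline's 95% slope and intercept
CIs cover the planted values at nominal-like rates (≥90/100 replicates is
the acceptance bar).

What the generator does **not** emulate: real English syntax or semantics,
genre-specific style, topical coherence between the trend corpus and real
discourse, raters who err asymmetrically, or collocates whose relevance a
human would reject. Passing tests therefore demonstrate that the machinery
measures what it claims on data satisfying its assumptions — not that any
particular historical corpus satisfies them.

`generate_topic_corpus` plants disjoint (or partially overlapping) topic
vocabularies with known document assignments and rating polarity
(positive topics rated 4–5, negative 1–2); recovery is scored by
best-permutation top-word purity (> 0.9 required) and by positivity
proportions within ±1 topic of truth.

## Numerical choices and degenerate inputs

- OLS fits require ≥3 points and nonconstant regressors; violations raise
  typed errors (`DataError`, `ComputationError`) rather than returning NaN.
- `percent_decline` requires a positive intercept.
- Cronbach's α requires ≥3 items, ≥2 raters, and nonzero total variance.
- In the ANOVA, an all-constant response yields F = 0, p = 1, η² = 0 rather
  than 0/0; a zero error SS with a nonzero effect reports F = ∞, p = 0.
- MI on any nonpositive count is a domain error; the independence point
  gives exactly 0 bits and doubling `N` adds exactly 1 bit (both tested).
- LDA topic order follows scikit-learn's seeded fit; ties in top-word
  ranking break by stable sort on descending probability, so runs are
  reproducible to the byte.
- CSV outputs carry a `# seed=… config_hash=…` header line; the hash covers
  analysis-relevant configuration only, so reruns into different
  directories compare equal.

## Problem sizes used by the shipped experiments

Replicated experiments (coverage, null calibration) use the reduced preset:
100 pipeline replicates for slope-CI coverage, 1,000 series-level
replicates for slope-test calibration, 1,000 simulated 40-unit tables for
ANOVA calibration, and 20 random ≤10k-token corpora for exact brute-force
equivalence. These sizes were chosen so the statistical assertions have
enough resolution (binomial SE ≤ 0.7 percentage points at 1,000 replicates)
while the whole suite stays fast to run routinely.

## Known limitations

- Age-based target terms default to the six published example synonyms;
  the full historical list is thesaurus work outside this package's scope,
  and the term lexicon is user-replaceable TSV for exactly that reason.
- MI-based retention has no significance test (log-likelihood, t-score are
  deliberately out of scope), so low-count high-MI pairs survive at
  `min_cooccurrence=1` unless configured otherwise.
- The trend model assumes homoscedastic, serially independent decade
  errors; real diachronic series may violate both.
- Topic-valence classification inherits every instability of small-corpus
  LDA; the neutral threshold sits at the center of the rating scale, so
  strata whose true valence hovers near 3 produce near-coin-flip labels —
  visible in the synthetic H2 outputs and expected there.
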