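"""Independent oracles: literal, brute-force re-implementations of the
window rules and closed-form statistics, kept deliberately separate from
the package's code paths."""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Brute-force collocation oracle
# ---------------------------------------------------------------------------


def brute_find_occurrences(sentences, term_tokens):
    """term_tokens: dict term-string -> tuple of tokens.  Longest match
    first, left to right, positions consumed."""
    by_len = sorted(term_tokens.items(), key=lambda kv: -len(kv[1]))
    out = []
    for s, sent in enumerate(sentences):
        i = 0
        while i < len(sent):
            hit = None
            for term, toks in by_len:
                if tuple(sent[i : i + len(toks)]) == toks:
                    hit = (term, len(toks))
                    break
            if hit:
                out.append((s, i, hit[0]))
                i += hit[1]
            else:
                i += 1
    return out


def brute_window(sentences, s, i, term_len, span, articles, sentence_initial_rule=True):
    """Literal double-loop window: flatten, walk outward position by
    position, skip articles without consuming span."""
    flat = [(si, ti, tok) for si, sent in enumerate(sentences) for ti, tok in enumerate(sent)]
    pos = {(si, ti): j for j, (si, ti, _) in enumerate(flat)}
    start = pos[(s, i)]
    end = start + term_len - 1

    left = []
    taken = 0
    j = start - 1
    while j >= 0 and taken < span:
        si, ti, tok = flat[j]
        if sentence_initial_rule and i == 0 and si < s:
            break
        if tok not in articles:
            left.append(tok)
            taken += 1
        j -= 1
    left.reverse()

    right = []
    taken = 0
    j = end + 1
    while j < len(flat) and taken < span:
        tok = flat[j][2]
        if tok not in articles:
            right.append(tok)
            taken += 1
        j += 1
    return left + right


def brute_collocate_counts(docs_sentences, term_tokens, span, articles, by_key):
    """(term, collocate, key) -> count and (term, key) -> occurrences, where
    docs_sentences is a list of (sentences, key)."""
    counts = {}
    tfreq = {}
    for sentences, key in docs_sentences:
        for s, i, term in brute_find_occurrences(sentences, term_tokens):
            tfreq[(term, key)] = tfreq.get((term, key), 0) + 1
            for tok in brute_window(sentences, s, i, len(term_tokens[term]), span, articles):
                k = (term, tok, key)
                counts[k] = counts.get(k, 0) + 1
    return counts, tfreq


def brute_marginals(docs_sentences):
    """key -> (N, word -> frequency), recounted one token at a time."""
    out = {}
    for sentences, key in docs_sentences:
        n, freqs = out.setdefault(key, [0, {}])
        for sent in sentences:
            for tok in sent:
                out[key][0] += 1
                freqs[tok] = freqs.get(tok, 0) + 1
    return {k: (v[0], v[1]) for k, v in out.items()}


def brute_mi(cooc, tf, cf, n, span):
    return math.log2(cooc * n / (tf * cf * 2 * span))


# ---------------------------------------------------------------------------
# Closed-form regression oracles
# ---------------------------------------------------------------------------


def ols_normal_equations(x, y):
    """Simple regression by explicit normal equations; returns
    (intercept, slope, se_intercept, se_slope)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det
    resid = y - intercept - slope * x
    mse = (resid**2).sum() / (n - 2)
    se_slope = math.sqrt(n * mse / det)
    se_intercept = math.sqrt(mse * sxx / det)
    return intercept, slope, se_intercept, se_slope


def interaction_f_normal_equations(x1, y1, x2, y2):
    """Pooled 4-parameter model [1, g, x, g*x] solved by explicit normal
    equations; returns the interaction F = t^2 and its residual df."""
    x = np.concatenate([x1, x2]).astype(float)
    g = np.concatenate([np.zeros(len(x1)), np.ones(len(x2))])
    y = np.concatenate([y1, y2]).astype(float)
    X = np.column_stack([np.ones_like(x), g, x, g * x])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = len(y) - 4
    mse = (resid**2).sum() / df
    cov = mse * np.linalg.inv(xtx)
    t = beta[3] / math.sqrt(cov[3, 3])
    return t * t, df


# ---------------------------------------------------------------------------
# Reliability and ANOVA oracles
# ---------------------------------------------------------------------------


def alpha_direct(ratings):
    """Cronbach's alpha straight from the definition."""
    x = np.asarray(ratings, float)
    n, k = x.shape
    item_vars = [np.var(x[:, j], ddof=1) for j in range(k)]
    total_var = np.var(x.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


def mixed_anova_2x2_hand(y_g1, y_g2):
    """Classical balanced split-plot decomposition for 2 groups x 2 within
    levels, computed from the textbook sums over cells.

    y_g1, y_g2: (n_g x 2) arrays.  Returns dict effect -> (ss, ss_err, F).
    """
    y = np.vstack([y_g1, y_g2])
    groups = np.array([0] * len(y_g1) + [1] * len(y_g2))
    k = 2
    grand = y.mean()
    # between-units stratum
    unit_means = y.mean(axis=1)
    ss_between_units = k * ((unit_means - grand) ** 2).sum()
    ss_a = 0.0
    for g in (0, 1):
        m = unit_means[groups == g].mean()
        ss_a += k * (groups == g).sum() * (m - grand) ** 2
    ss_subj = ss_between_units - ss_a
    # within-units stratum
    ss_within_units = ((y - unit_means[:, None]) ** 2).sum()
    col_means = y.mean(axis=0)
    ss_b = len(y) * ((col_means - grand) ** 2).sum()
    ss_ab = 0.0
    for g in (0, 1):
        sub = y[groups == g]
        for b in (0, 1):
            cell = sub[:, b].mean()
            ss_ab += len(sub) * (cell - sub.mean() - col_means[b] + grand) ** 2
    ss_resid = ss_within_units - ss_b - ss_ab
    n = len(y)
    out = {
        "between": (ss_a, ss_subj, (ss_a / 1) / (ss_subj / (n - 2))),
        "within": (ss_b, ss_resid, (ss_b / 1) / (ss_resid / (n - 2))),
        "interaction": (ss_ab, ss_resid, (ss_ab / 1) / (ss_resid / (n - 2))),
    }
    return out
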