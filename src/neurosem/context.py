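"""Context dependence of semantic tuning.

Three complementary probes: (1) homophone pairs — identical sound, different
meaning — dissociate semantic from phonetic coding via a pooled permutation
test on absolute firing-rate differences; (2) sentence vs word-list SI
contrasts measure how much tuning depends on sentence context (paired
signed-rank); (3) surprisal — the negative log conditional probability of a
word given its preceding words — conditions decoding accuracy on
predictability (top vs bottom deciles). A leave-one-out session-dropping
procedure checks that no single participant drives a result.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for
from .alignment import ResponseMatrix, select_events
from .decoding import DecoderConfig, decode_domains
from .embeddings import DomainPartition
from .selectivity import domain_selectivity, selectivity_index
from .synthetic import WordEvent

__all__ = [
    "LanguageModel",
    "BackoffBigramModel",
    "surprisal",
    "surprisal_decile_decoding",
    "homophone_contrast",
    "sentence_vs_wordlist_si",
    "participant_dropout",
]


class LanguageModel(Protocol):
    """Conditional word-probability interface (natural-log surprisal).

    Any model exposing cond_prob can back the surprisal analysis — the
    package default is a backoff bigram fit on the session corpus; a
    pretrained neural model can be wrapped behind the same method for real
    recordings.
    """

    def cond_prob(self, word: str, prefix: tuple[str, ...]) -> float:
        """P(word | prefix), in (0, 1]."""
        ...


class BackoffBigramModel:
    """Absolute-discounting bigram with add-one unigram backoff.

    P(w | prev) = max(c(prev, w) - D, 0) / c(prev) + lambda(prev) * P1(w)
    where lambda(prev) releases exactly the discounted mass and
    P1(w) = (c(w) + 1) / (N + V) over the training vocabulary, so the
    conditional distribution sums to 1 over the vocabulary.
    """

    def __init__(self, sentences: list[list[str]], discount: float = 0.5):
        if not 0 < discount < 1:
            raise ValueError("discount must lie in (0, 1)")
        self.discount = discount
        self.unigrams: Counter = Counter()
        self.bigrams: Counter = Counter()
        for sent in sentences:
            for w in sent:
                self.unigrams[w] += 1
            for a, b in zip(sent, sent[1:]):
                self.bigrams[(a, b)] += 1
        self.vocab = sorted(self.unigrams)
        self._n = sum(self.unigrams.values())
        self._v = len(self.vocab)
        self._prev_total: Counter = Counter()
        self._prev_types: Counter = Counter()
        for (a, _), c in self.bigrams.items():
            self._prev_total[a] += c
            self._prev_types[a] += 1

    def _p1(self, word: str) -> float:
        return (self.unigrams.get(word, 0) + 1) / (self._n + self._v)

    def cond_prob(self, word: str, prefix: tuple[str, ...]) -> float:
        if not prefix:
            return self._p1(word)
        prev = prefix[-1]
        total = self._prev_total.get(prev, 0)
        if total == 0:
            return self._p1(word)
        c_big = self.bigrams.get((prev, word), 0)
        lam = self.discount * self._prev_types[prev] / total
        return max(c_big - self.discount, 0.0) / total + lam * self._p1(word)


def surprisal(
    events: list[WordEvent] | pd.DataFrame,
    lm: LanguageModel,
    max_surprisal: float = 30.0,
) -> np.ndarray:
    """Per-word surprisal -ln P(w_i | w_1..w_{i-1}) within each sentence.

    The first word of a sentence is conditioned on the empty prefix. Only
    sentence-condition events are scored; other rows get NaN. Zero
    probabilities are capped at `max_surprisal` with a warning.
    """
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        from .synthetic import events_to_frame
        df = events_to_frame(events)
    out = np.full(len(df), np.nan)
    capped = 0
    for sid, grp in df[df["condition"] == "sentence"].groupby("sentence_id"):
        grp = grp.sort_values("position")
        prefix: tuple[str, ...] = ()
        for idx, row in zip(grp.index, grp.itertuples(index=False)):
            p = lm.cond_prob(row.token, prefix)
            if p <= 0:
                capped += 1
                s = max_surprisal
            else:
                s = min(-math.log(p), max_surprisal)
            out[df.index.get_loc(idx)] = s
            prefix = prefix + (row.token,)
    if capped:
        warnings.warn(f"{capped} zero-probability words capped at {max_surprisal}")
    return out


def surprisal_decile_decoding(
    matrix: ResponseMatrix,
    partition: DomainPartition | None,
    units,
    surprisals: np.ndarray,
    cfg: DecoderConfig | None = None,
    n_iterations: int = 200,
    n_quantiles: int = 10,
) -> dict:
    """Decoding accuracy for predictable (bottom-decile surprisal) vs
    unpredictable (top-decile) words.

    Runs the standard sentence-split decoder tracking per-event correctness;
    accuracy is aggregated per event across held-out appearances, and the
    low/high decile groups are compared by rank-sum over per-event accuracy
    rates. Deciles widen to quintiles when a decile would hold <10 words.
    """
    cfg = cfg or DecoderConfig()
    surprisals = np.asarray(surprisals, dtype=float)
    if len(surprisals) != matrix.n_events:
        raise ValueError("surprisals must align with matrix events")
    sent = select_events(matrix, conditions="sentence")
    s_sent = surprisals[matrix.events["condition"].to_numpy() == "sentence"]
    scored = np.isfinite(s_sent)
    if scored.sum() // n_quantiles < 10 and n_quantiles > 5:
        warnings.warn("fewer than 10 words per decile; widening to quintiles")
        n_quantiles = 5
    edges = np.quantile(s_sent[scored], np.linspace(0, 1, n_quantiles + 1))
    lo_mask = scored & (s_sent <= edges[1])
    hi_mask = scored & (s_sent >= edges[-2])
    res = decode_domains(sent, partition, units, cfg, n_iterations=n_iterations,
                         track_events=True)
    word_mask = sent.events["domain"].notna().to_numpy()
    rate = res.per_event_rate()
    # per-event rates live on word events only
    full_rate = np.full(len(sent.events), np.nan)
    full_rate[np.flatnonzero(word_mask)] = rate
    lo = full_rate[lo_mask & word_mask]
    hi = full_rate[hi_mask & word_mask]
    lo, hi = lo[np.isfinite(lo)], hi[np.isfinite(hi)]
    z, p = stats.ranksums(lo, hi)
    return {
        "acc_low_decile": float(np.mean(lo)),
        "acc_high_decile": float(np.mean(hi)),
        "z": float(z),
        "p": float(p),
        "n_low": int(len(lo)),
        "n_high": int(len(hi)),
        "n_quantiles": n_quantiles,
    }


# ---------------------------------------------------------------------------
# Homophones
# ---------------------------------------------------------------------------

def _pair_abs_diffs(matrix: ResponseMatrix, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Per-unit mean |rate(a) - rate(b)| over word pairs (NaN-safe)."""
    tokens = matrix.events["token"].to_numpy()
    out = np.full((matrix.n_units, len(pairs)), np.nan)
    for j, (a, b) in enumerate(pairs):
        ma, mb = tokens == a, tokens == b
        if not ma.any() or not mb.any():
            continue
        out[:, j] = np.abs(matrix.rates[:, ma].mean(axis=1)
                           - matrix.rates[:, mb].mean(axis=1))
    return np.nanmean(out, axis=1)


def homophone_contrast(
    matrix: ResponseMatrix,
    events: pd.DataFrame | list[WordEvent],
    partition: DomainPartition,
    units: list[int] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    iqr_factor: float = 2.5,
) -> dict:
    """Homophone vs non-homophone response contrast.

    Per unit: mean |delta rate| over homophone pairs (same sound, different
    domain) vs over sampled same-domain non-homophone pairs (matched in
    count and, to equalise sampling-noise floors, in token frequency). A
    pooled two-sided permutation test (default 10,000 shuffles) compares the
    two distributions; a one-tailed paired t-test checks the per-unit scatter
    against the identity line. Units with no response or lying beyond
    `iqr_factor` times the interquartile range are excluded and reported.
    Pass the semantically selective units via `units` for the headline
    contrast. To pool several sessions/participants (as the recorded data
    were), pass lists of matrices, event tables, and unit subsets of equal
    length; per-unit measurements are concatenated before testing.
    """
    if isinstance(matrix, (list, tuple)):
        xs, ys, n_pairs_total = [], [], 0
        parts = list(partition) if isinstance(partition, (list, tuple)) else [
            partition] * len(matrix)
        unit_sets = units if units is not None else [None] * len(matrix)
        for m_s, e_s, p_s, u_s in zip(matrix, events, parts, unit_sets):
            x_s, y_s, n_p = _session_pair_diffs(m_s, e_s, p_s, u_s, seed)
            xs.append(x_s)
            ys.append(y_s)
            n_pairs_total += n_p
        return _homophone_test(np.concatenate(xs), np.concatenate(ys),
                               n_pairs_total, n_perm, seed, iqr_factor)
    x, y, n_pairs = _session_pair_diffs(matrix, events, partition, units, seed)
    return _homophone_test(x, y, n_pairs, n_perm, seed, iqr_factor)


def _session_pair_diffs(matrix, events, partition, units, seed):
    """Per-unit homophone and matched non-homophone |delta rate| for one
    session; returns (x, y, n_pairs)."""
    if isinstance(events, list):
        from .synthetic import events_to_frame
        events = events_to_frame(events)
    if units is not None:
        matrix = matrix.subset_units(units)
    matrix = select_events(matrix, conditions="sentence")
    sent = events[events["condition"] == "sentence"]
    by_pid: dict[str, set[str]] = {}
    for row in sent.itertuples(index=False):
        by_pid.setdefault(row.phonetic_id, set()).add(row.token)
    homophones = [tuple(sorted(v)) for v in by_pid.values() if len(v) == 2]
    homophones = [
        (a, b) for a, b in homophones
        if partition.domain_of(a) != partition.domain_of(b)
    ]
    if not homophones:
        raise ValueError("no cross-domain homophone pairs in the events")

    # same-domain, different-sound comparison pairs: one per homophone pair,
    # drawn from the words whose occurrence counts best match the pair's
    rng = rng_for(seed, "homophone_pairs")
    counts = Counter(sent["token"])
    homo_words = {w for p in homophones for w in p}
    non_pairs: list[tuple[str, str]] = []
    by_domain: dict[int, list[str]] = {}
    for t in sorted(set(sent["token"])):
        if t in homo_words:
            continue
        by_domain.setdefault(partition.domain_of(t), []).append(t)
    domains = [d for d, ws in sorted(by_domain.items()) if len(ws) >= 2]
    used: set[str] = set()
    for a, b in homophones:
        best = None
        for d in domains:
            cands = [w for w in by_domain[d] if w not in used]
            if len(cands) < 2:
                cands = by_domain[d]
            u = min(cands, key=lambda w: (abs(counts[w] - counts[a]), w))
            v = min((w for w in cands if w != u),
                    key=lambda w: (abs(counts[w] - counts[b]), w))
            cost = abs(counts[u] - counts[a]) + abs(counts[v] - counts[b])
            if best is None or cost < best[0]:
                best = (cost, u, v)
        _, u, v = best
        used.update((u, v))
        non_pairs.append((u, v))

    x = _pair_abs_diffs(matrix, homophones)  # homophone |delta|
    y = _pair_abs_diffs(matrix, non_pairs)  # same-domain |delta|
    # mark no-response units for downstream exclusion
    responded = matrix.rates.sum(axis=1) > 0
    x = np.where(responded, x, np.nan)
    y = np.where(responded, y, np.nan)
    return x, y, len(homophones)


def _homophone_test(x, y, n_pairs, n_perm, seed, iqr_factor):
    # exclusions: no response (NaN), or outside iqr_factor x IQR
    finite = np.isfinite(x) & np.isfinite(y)
    pooled0 = np.concatenate([x[finite], y[finite]])
    q1, q3 = np.percentile(pooled0, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
    with np.errstate(invalid="ignore"):
        keep = finite & (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]

    observed = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    rng_p = rng_for(seed, "homophone_perm")
    count = 0
    for _ in range(n_perm):
        perm = rng_p.permutation(pooled)
        diff = perm[: len(x)].mean() - perm[len(x):].mean()
        if abs(diff) >= abs(observed):
            count += 1
    p_perm = max(count / n_perm, 1.0 / n_perm)
    t_stat, p_two = stats.ttest_rel(x, y)
    # one-tailed: homophone |delta| exceeds same-domain |delta|
    p_t = p_two / 2 if t_stat > 0 else 1 - p_two / 2
    return {
        "delta_homophone": float(x.mean()),
        "delta_nonhomophone": float(y.mean()),
        "observed_diff": observed,
        "p_permutation": float(p_perm),
        "t": float(t_stat),
        "p_t_onetailed": float(p_t),
        "n_units": int(len(x)),
        "n_excluded": n_excluded,
        "n_pairs": n_pairs,
        "scatter": pd.DataFrame({"homophone": x, "nonhomophone": y}),
    }


def sentence_vs_wordlist_si(
    matrix: ResponseMatrix,
    partition: DomainPartition,
    units: list[int] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Paired sentence vs word-list SI for semantically selective units.

    Units are selected (and their preferred domain fixed) on the sentence
    condition; SI is then recomputed per condition. Returns the signed-rank
    test on SIs and a companion rank-sum on overall mean rates, which should
    be null when only tuning gain (not baseline) is attenuated.
    """
    sent = select_events(matrix, conditions="sentence")
    try:
        wl = select_events(matrix, conditions="word_list")
    except ValueError as e:
        raise ValueError("word_list condition absent") from e
    res = domain_selectivity(sent, partition, alpha)
    if units is None:
        units = res.selective_units()
    si_s, si_w, used = [], [], []
    for u in units:
        d = res.units[u].preferred_domain
        if d is None:
            continue
        wl_dom = wl.events["domain"].to_numpy() == d
        if not wl_dom.any() or wl_dom.all():
            warnings.warn(f"unit {u}: no word-list events in domain {d}; excluded")
            continue
        a = selectivity_index(sent, partition, u, d)
        b = selectivity_index(wl, partition, u, d)
        if np.isfinite(a) and np.isfinite(b):
            si_s.append(a)
            si_w.append(b)
            used.append(u)
    si_s, si_w = np.asarray(si_s), np.asarray(si_w)
    if len(si_s) == 0:
        raise ValueError("no usable units for sentence/word-list contrast")
    diffs = si_s - si_w
    if np.allclose(diffs, 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(si_s, si_w)
    mean_s = sent.rates.mean(axis=1)
    mean_w = wl.rates.mean(axis=1)
    z_rate, p_rate = stats.ranksums(mean_s, mean_w)
    return {
        "si_sentence": float(si_s.mean()),
        "si_wordlist": float(si_w.mean()),
        "signed_rank_stat": float(stat),
        "p": float(p),
        "units": used,
        "rate_z": float(z_rate),
        "rate_p": float(p_rate),
    }


def participant_dropout(
    analysis,
    sessions: list,
    alpha: float = 0.05,
) -> dict:
    """Leave-one-out robustness over sessions/participants.

    `analysis` is a callable taking a list of sessions and returning a dict
    with at least {"p": float} and optionally {"values": array} (per-unit or
    per-word values entering the statistic). The analysis is rerun with each
    session removed; a dropout is flagged when its significance decision
    differs from the full dataset's, and a one-way ANOVA across dropout value
    distributions checks homogeneity.
    """
    if len(sessions) < 3:
        raise ValueError("participant dropout needs at least 3 sessions")
    if not callable(analysis):
        raise TypeError("analysis must be a rerunnable callable over sessions")
    full = analysis(sessions)
    full_sig = full["p"] < alpha
    per_dropout = []
    flagged = []
    value_sets = []
    for i in range(len(sessions)):
        sub = sessions[:i] + sessions[i + 1:]
        res = analysis(sub)
        per_dropout.append(res)
        if (res["p"] < alpha) != full_sig:
            flagged.append(i)
        if "values" in res:
            value_sets.append(np.asarray(res["values"], dtype=float))
    anova_p = None
    if len(value_sets) == len(sessions) and all(len(v) > 1 for v in value_sets):
        _, anova_p = stats.f_oneway(*value_sets)
        anova_p = float(anova_p)
    return {
        "full": full,
        "per_dropout": per_dropout,
        "flagged_sessions": flagged,
        "n_dropouts": len(per_dropout),
        "anova_p": anova_p,
    }
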