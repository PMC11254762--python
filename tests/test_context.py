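"""Context dependence: surprisal, homophones, word lists, session dropout."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import neurosem as ns
from neurosem.pipeline import _sentences_of
from neurosem.synthetic import events_to_frame


class FixedLM:
    """Language model returning a constant conditional probability."""

    def __init__(self, p):
        self.p = p

    def cond_prob(self, word, prefix):
        return self.p


def _sentence_frame(sentences):
    rows = []
    t = 0.0
    for sid, sent in enumerate(sentences):
        for pos, tok in enumerate(sent, start=1):
            rows.append({"token": tok, "phonetic_id": tok, "onset": t,
                         "condition": "sentence", "sentence_id": sid,
                         "position": pos, "domain": 1})
            t += 0.341
    return pd.DataFrame(rows)


class TestSurprisal:
    def test_certain_word_is_zero(self):
        df = _sentence_frame([["a", "b"]])
        s = ns.surprisal(df, FixedLM(1.0))
        np.testing.assert_allclose(s, 0.0)

    def test_closed_form(self):
        df = _sentence_frame([["a"]])
        s = ns.surprisal(df, FixedLM(math.exp(-2)))
        assert s[0] == pytest.approx(2.0)

    def test_zero_probability_capped(self):
        df = _sentence_frame([["a"]])
        with pytest.warns(UserWarning, match="capped"):
            s = ns.surprisal(df, FixedLM(0.0), max_surprisal=25.0)
        assert s[0] == 25.0

    def test_bigram_matches_hand_counts(self):
        """Backoff bigram on a tiny corpus against hand-computed
        absolute-discounting probabilities."""
        corpus = [["the", "cat", "sat"], ["the", "dog", "sat"],
                  ["the", "cat", "ran"]] * 2
        lm = ns.BackoffBigramModel(corpus, discount=0.5)
        # unigram counts: the=6, cat=4, sat=4, dog=2, ran=2; N=18, V=5
        assert lm.cond_prob("the", ()) == pytest.approx(7 / 23)
        # bigram (the -> cat): c=4 of 6 'the' bigram starts; types after 'the'=2
        p1_cat = (4 + 1) / (18 + 5)
        expected = (4 - 0.5) / 6 + (0.5 * 2 / 6) * p1_cat
        assert lm.cond_prob("cat", ("the",)) == pytest.approx(expected)
        # unseen bigram backs off to the discounted unigram mass
        p1_dog = (2 + 1) / 23
        assert lm.cond_prob("dog", ("cat",)) == pytest.approx(
            (0.5 * 2 / 4) * p1_dog)

    def test_conditional_sums_to_at_most_one(self):
        corpus = [["a", "b", "c", "a", "b"], ["b", "a", "c"]]
        lm = ns.BackoffBigramModel(corpus)
        for prev in ["a", "b", "c"]:
            total = sum(lm.cond_prob(w, (prev,)) for w in lm.vocab)
            assert total <= 1 + 1e-9

    def test_additive_over_sentence(self):
        """Chain rule: surprisals sum to -ln P(sentence)."""
        corpus = [["a", "b", "c"], ["a", "c", "b"], ["b", "a", "c"]]
        lm = ns.BackoffBigramModel(corpus)
        sent = ["a", "b", "c"]
        df = _sentence_frame([sent])
        s = ns.surprisal(df, lm)
        logp = 0.0
        prefix = ()
        for w in sent:
            logp += math.log(lm.cond_prob(w, prefix))
            prefix += (w,)
        assert s.sum() == pytest.approx(-logp)

    def test_decile_boundaries_match_quantile_oracle(self, default_session,
                                                     default_matrix):
        sent_events = [e for e in default_session.events
                       if e.condition == "sentence"]
        lm = ns.BackoffBigramModel(_sentences_of(sent_events))
        s = ns.surprisal(default_matrix.events, lm)
        vals = s[np.isfinite(s)]
        lo_edge = np.quantile(vals, 0.1)
        # oracle: sorting
        srt = np.sort(vals)
        assert lo_edge == pytest.approx(
            np.quantile(srt, 0.1))
        assert (vals <= lo_edge).mean() >= 0.1 - 1e-9


@pytest.fixture(scope="module")
def surprisal_world():
    """Session whose tuning gain scales with word predictability."""
    cfg = ns.GeneratorConfig(seed=5, surprisal_sensitivity=0.9)
    table, part = ns.generate_embedding_space(cfg)
    events = ns.generate_stimuli(cfg, part)
    lm = ns.BackoffBigramModel(
        _sentences_of([e for e in events if e.condition == "sentence"]))
    surp = ns.surprisal(events_to_frame(events), lm)
    finite = np.isfinite(surp)
    pred = np.zeros(len(surp))
    ranks = surp[finite].argsort().argsort()
    pred[finite] = 1.0 - ranks / (finite.sum() - 1)
    spikes = ns.simulate_population(cfg, events, part, predictability=pred)
    m = ns.align_responses(spikes, events)
    return cfg, part, m, surp


@pytest.fixture(scope="module")
def dropout_sessions():
    return [ns.generate_session(ns.GeneratorConfig(
        seed=30 + i, n_units=30, n_sentences=40, nonword_blocks=0,
        story_vocab_new=0, story_vocab_shared=0, n_story_sentences=0))
        for i in range(4)]


class TestSurprisalDecoding:
    def test_predictable_words_decode_better(self, surprisal_world):
        cfg, part, m, surp = surprisal_world
        sent = ns.select_events(m, conditions="sentence")
        sel = ns.domain_selectivity(sent, part).selective_units()
        res = ns.surprisal_decile_decoding(m, part, sel, surp,
                                           n_iterations=40)
        assert res["acc_low_decile"] > res["acc_high_decile"]
        assert res["p"] < 0.05

    def test_insensitive_world_shows_no_effect(self):
        cfg = ns.GeneratorConfig(seed=6)  # surprisal_sensitivity = 0
        s = ns.generate_session(cfg)
        m = ns.align_responses(s.spikes, s.events)
        lm = ns.BackoffBigramModel(
            _sentences_of([e for e in s.events if e.condition == "sentence"]))
        surp = ns.surprisal(m.events, lm)
        sent = ns.select_events(m, conditions="sentence")
        sel = ns.domain_selectivity(sent, s.partition).selective_units()
        res = ns.surprisal_decile_decoding(m, s.partition, sel, surp,
                                           n_iterations=40)
        assert res["p"] > 0.05


class TestHomophoneContrast:
    def test_meaning_coding_recovered_pooled(self):
        """Across pooled sessions, homophone |delta| exceeds same-domain
        |delta| for the selective population (meaning, not sound, coding)."""
        mats, evs, parts, units = [], [], [], []
        for seed in (11, 12, 13):
            s = ns.generate_session(ns.GeneratorConfig(seed=seed))
            m = ns.align_responses(s.spikes, s.events)
            sent = ns.select_events(m, conditions="sentence")
            sel = ns.domain_selectivity(sent, s.partition).selective_units()
            mats.append(m)
            evs.append(m.events)
            parts.append(s.partition)
            units.append(sel)
        hc = ns.homophone_contrast(mats, evs, parts, units=units,
                                   n_perm=2000, seed=0)
        assert hc["delta_homophone"] > hc["delta_nonhomophone"]
        assert hc["p_permutation"] < 0.01
        assert hc["p_t_onetailed"] < 0.01

    def test_phonetic_coding_reverses(self):
        """Sound-coding control: units respond to phonetic ids, so homophone
        mates elicit identical responses and the contrast flips sign."""
        s = ns.generate_session(ns.GeneratorConfig(seed=3, phonetic_mode=True))
        m = ns.align_responses(s.spikes, s.events)
        hc = ns.homophone_contrast(m, m.events, s.partition,
                                   units=s.spikes.selective_units(),
                                   n_perm=1000, seed=3)
        assert hc["delta_homophone"] < hc["delta_nonhomophone"]
        assert hc["t"] < 0

    def test_degenerate_identical_responses(self, small_session):
        m = ns.align_responses(small_session.spikes, small_session.events)
        flat = ns.alignment.ResponseMatrix(
            np.ones_like(m.rates), m.unit_ids, m.events, m.window)
        hc = ns.homophone_contrast(flat, m.events, small_session.partition,
                                   n_perm=500, seed=0)
        assert hc["observed_diff"] == 0.0
        assert hc["p_permutation"] > 0.9

    def test_no_homophones_errors(self):
        cfg = ns.GeneratorConfig(n_domains=3, words_per_domain=6, dim=8,
                                 n_sentences=10, homophone_pairs=0,
                                 nonword_blocks=0, story_vocab_new=0,
                                 story_vocab_shared=0, n_story_sentences=0,
                                 n_units=5, seed=0)
        s = ns.generate_session(cfg)
        m = ns.align_responses(s.spikes, s.events)
        with pytest.raises(ValueError, match="homophone"):
            ns.homophone_contrast(m, m.events, s.partition, n_perm=10, seed=0)


class TestSentenceVsWordlist:
    def test_attenuation_detected(self, default_session, default_matrix):
        """gamma = 0.5: word-list SI drops below sentence SI (signed-rank)."""
        res = ns.sentence_vs_wordlist_si(default_matrix,
                                         default_session.partition)
        assert res["si_wordlist"] < res["si_sentence"]
        assert res["p"] < 0.05
        # mean rates are matched by construction: companion test is null
        assert res["rate_p"] > 0.05

    def test_no_attenuation_calibrated(self):
        s = ns.generate_session(ns.GeneratorConfig(seed=8,
                                                   context_attenuation=1.0))
        m = ns.align_responses(s.spikes, s.events)
        res = ns.sentence_vs_wordlist_si(m, s.partition)
        assert res["p"] > 0.05

    def test_missing_wordlists_error(self):
        cfg = ns.GeneratorConfig(n_domains=3, words_per_domain=8, dim=8,
                                 n_sentences=12, n_wordlist_sentences=0,
                                 nonword_blocks=0, homophone_pairs=0,
                                 story_vocab_new=0, story_vocab_shared=0,
                                 n_story_sentences=0, n_units=10, seed=1)
        s = ns.generate_session(cfg)
        m = ns.align_responses(s.spikes, s.events)
        with pytest.raises(ValueError, match="word_list"):
            ns.sentence_vs_wordlist_si(m, s.partition)


class TestParticipantDropout:
    @staticmethod
    def _analysis(sessions):
        """Mean SI of planted selective units pooled over sessions, with a
        one-sample test against zero."""
        from scipy import stats as sps

        vals = []
        for s in sessions:
            m = ns.align_responses(s.spikes, s.events)
            sent = ns.select_events(m, conditions="sentence")
            for u in s.spikes.selective_units():
                d = s.spikes.ground_truth[u]["preferred_domain"]
                vals.append(ns.selectivity_index(sent, s.partition, u, d))
        vals = np.asarray(vals)
        t, p = sps.ttest_1samp(vals, 0.0)
        return {"p": float(p), "statistic": float(t), "values": vals}

    def test_homogeneous_sessions_agree(self, dropout_sessions):
        sessions = dropout_sessions
        out = ns.participant_dropout(self._analysis, sessions)
        assert out["n_dropouts"] == len(sessions)
        assert out["flagged_sessions"] == []
        assert out["anova_p"] is None or out["anova_p"] > 0.01

    def test_requires_three_sessions(self, dropout_sessions):
        sessions = dropout_sessions
        with pytest.raises(ValueError):
            ns.participant_dropout(self._analysis, sessions[:2])

    def test_rejects_non_callable(self, dropout_sessions):
        sessions = dropout_sessions
        with pytest.raises(TypeError):
            ns.participant_dropout("not-an-analysis", sessions)

    def test_planted_outlier_flagged(self, dropout_sessions):
        sessions = dropout_sessions
        """One session with no tuning at all pulls the pooled statistic; its
        removal flips significance of a tight criterion."""
        outlier = ns.generate_session(ns.GeneratorConfig(
            seed=99, n_units=30, n_sentences=40, tuning_gain=0.0,
            frac_selective=0.15, nonword_blocks=0, story_vocab_new=0,
            story_vocab_shared=0, n_story_sentences=0))

        def analysis(sess):
            base = self._analysis(sess)
            # criterion: mean planted SI above 0.2
            from scipy import stats as sps
            t, p = sps.ttest_1samp(base["values"], 0.2)
            one_sided = p / 2 if t > 0 else 1 - p / 2
            return {"p": float(one_sided), "values": base["values"]}

        out = ns.participant_dropout(analysis, sessions[:3] + [outlier])
        assert out["flagged_sessions"] == [3]
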