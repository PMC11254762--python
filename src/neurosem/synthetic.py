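"""Synthetic semantically tuned spiking populations and their stimuli.

The generator emulates a single intraoperative session: a vocabulary of words
with planted semantic-domain structure on the unit sphere, a naturalistic
stimulus stream (eight-word sentences, token-shuffled word lists, nonword
blocks, cross-domain homophone pairs, and a story with partially novel
vocabulary), and Poisson spiking units a subset of which is tuned to a
preferred domain.

Scale defaults mirror the recorded sessions: 133 units of which ~15% are
semantically selective, 9 domains, 51 words per domain (459 unique words),
131 eight-word sentences (1,048 tokens), 341 +- 5 ms word spacing, and a
story vocabulary of 70 words of which 28 are shared with the sentences.

Rate defaults (baseline 2 Hz, tuning gain 2.3 Hz) are tuned analytically so
that the *measured* selectivity index of a planted unit is ~0.3 once the
400-ms analysis window's 59-ms overlap with each neighbouring word is
accounted for; the word-list attenuation gamma = 0.5 then yields a measured
SI near 0.18, emulating the sentence -> word-list selectivity drop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import rng_for
from .embeddings import DomainPartition, EmbeddingTable

__all__ = [
    "GeneratorConfig",
    "WordEvent",
    "SpikeData",
    "SyntheticSession",
    "generate_embedding_space",
    "generate_stimuli",
    "simulate_population",
    "generate_session",
    "events_to_frame",
    "frame_to_events",
]

CONDITIONS = ("sentence", "word_list", "nonword", "story")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world, with session-scale defaults."""

    n_domains: int = 9
    words_per_domain: int = 51
    dim: int = 300
    concentration: float = 25.0  # word = normalize(centroid + noise/concentration)
    n_sentences: int = 131
    sentence_length: int = 8
    n_units: int = 133
    frac_selective: float = 0.15
    baseline_rate: float = 2.0  # Hz
    tuning_gain: float = 2.3  # Hz added for preferred-domain words
    context_attenuation: float = 0.5  # gamma: gain multiplier in word lists
    n_wordlist_sentences: int | None = None  # None -> all sentences re-shuffled
    homophone_pairs: int = 12
    min_homophone_occurrences: int = 8  # boost pair/control word recurrence
    nonword_blocks: int = 5
    story_vocab_new: int = 42
    story_vocab_shared: int = 28
    n_story_sentences: int = 20
    inter_onset: float = 0.341  # s, mean word spacing
    onset_jitter: float = 0.005  # s, sd of spacing jitter (truncated at 0)
    window_lag: float = 0.1  # s, response window start relative to onset
    window_dur: float = 0.4  # s, response window length
    nonword_discriminability: float = 0.5  # rate drop for nonwords
    frac_nonword_discriminating: float = 0.5
    geometry_mode: bool = False  # gain follows cosine to preferred direction
    phonetic_mode: bool = False  # control: units prefer sounds, not meanings
    surprisal_sensitivity: float = 0.0  # beta: gain scaling by predictability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.tuning_gain < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.context_attenuation <= 1.0:
            raise ValueError("context_attenuation must lie in [0, 1]")
        if self.sentence_length < 2:
            raise ValueError("sentence_length must be >= 2")
        if self.story_vocab_shared > self.words_per_domain * self.n_domains:
            raise ValueError("story shared vocabulary exceeds sentence vocabulary")


@dataclass
class WordEvent:
    """One time-stamped token presentation."""

    token: str
    phonetic_id: str
    onset: float  # s
    condition: str  # sentence | word_list | nonword | story
    sentence_id: int
    position: int  # 1..sentence_length
    domain: int | None  # ground-truth domain; None for nonwords


@dataclass
class SpikeData:
    """Per-unit sorted spike-time lists with generator ground truth."""

    spikes: dict[int, np.ndarray]  # unit_id -> sorted times (s)
    ground_truth: dict[int, dict]  # unit_id -> {selective, preferred_domain}

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.spikes)

    def selective_units(self) -> list[int]:
        return [u for u in self.unit_ids if self.ground_truth[u]["selective"]]

    def write(self, directory) -> None:
        """One newline-separated times file per unit plus a manifest JSON."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {"units": {}}
        for u in self.unit_ids:
            fname = f"unit_{u:04d}.txt"
            np.savetxt(d / fname, self.spikes[u], fmt="%.6f")
            manifest["units"][str(u)] = {"file": fname, **self.ground_truth[u]}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def read(cls, directory) -> "SpikeData":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        spikes, truth = {}, {}
        for u_str, meta in manifest["units"].items():
            u = int(u_str)
            spikes[u] = np.atleast_1d(np.loadtxt(d / meta["file"]))
            truth[u] = {k: v for k, v in meta.items() if k != "file"}
        return cls(spikes, truth)


@dataclass
class SyntheticSession:
    """A fully generated session: embeddings, domains, stimuli, and spikes."""

    table: EmbeddingTable
    partition: DomainPartition
    events: list[WordEvent]
    spikes: SpikeData
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Embedding space with planted domains
# ---------------------------------------------------------------------------

def generate_embedding_space(
    cfg: GeneratorConfig,
) -> tuple[EmbeddingTable, DomainPartition]:
    """Plant `n_domains` vMF-like word clusters around orthonormal centroids.

    Word vectors are normalize(centroid + eps / concentration) with standard
    normal eps, so larger concentration means tighter domains. Story-novel
    words (named "s<domain>_<i>") are appended to the vocabulary with the same
    geometry when the story condition is configured.
    """
    if cfg.dim < cfg.n_domains:
        raise ValueError("dim < n_domains: cannot place separated centroids")
    if cfg.words_per_domain * cfg.n_domains < 2:
        raise ValueError("need at least 2 words")
    rng = rng_for(cfg.seed, "space")
    # orthonormal centroids via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.standard_normal((cfg.dim, cfg.n_domains)))
    centroids = q.T

    words: list[str] = []
    vecs: list[np.ndarray] = []
    assignment: dict[str, int] = {}

    def add_word(name: str, domain: int) -> None:
        noise = rng.standard_normal(cfg.dim) / cfg.concentration if np.isfinite(
            cfg.concentration
        ) else 0.0
        v = centroids[domain - 1] + noise
        v = v / np.linalg.norm(v)
        words.append(name)
        vecs.append(v)
        assignment[name] = domain

    for d in range(1, cfg.n_domains + 1):
        for i in range(cfg.words_per_domain):
            add_word(f"w{d}_{i}", d)
    for i in range(cfg.story_vocab_new):
        d = i % cfg.n_domains + 1
        add_word(f"s{d}_{i}", d)
    table = EmbeddingTable(words, np.vstack(vecs))
    return table, DomainPartition(assignment, centroids)


# ---------------------------------------------------------------------------
# Stimulus stream
# ---------------------------------------------------------------------------

def _deal_tokens(vocab: list[str], n_tokens: int, rng: np.random.Generator) -> list[str]:
    """Cover the whole vocabulary first, then fill with uniform draws."""
    tokens = list(rng.permutation(vocab))
    while len(tokens) < n_tokens:
        tokens.extend(rng.choice(vocab, size=min(len(vocab), n_tokens - len(tokens)),
                                 replace=True))
    return tokens[:n_tokens]


def generate_stimuli(
    cfg: GeneratorConfig, partition: DomainPartition, seed: int | None = None
) -> list[WordEvent]:
    """Build the full time-stamped stimulus stream for one session.

    Sentences sample the sentence vocabulary (every word is heard at least
    once when the token budget allows); word lists are token-shuffled copies
    of sentences sharing their sentence_id; homophone mates share a
    phonetic_id but come from different domains; nonwords carry no domain; the
    story reuses `story_vocab_shared` sentence words plus the story-novel
    vocabulary.
    """
    seed = cfg.seed if seed is None else seed
    rng = rng_for(seed, "stimuli")
    sentence_vocab = sorted(w for w in partition.words if w.startswith("w"))
    if len(sentence_vocab) < cfg.sentence_length:
        raise ValueError("vocabulary smaller than one sentence")

    # --- homophone pairs: same sound, different domains -------------------
    phonetic_id = {w: w for w in partition.words}
    boost_words: list[str] = []
    n_pairs = cfg.homophone_pairs
    if n_pairs > 0:
        by_domain: dict[int, list[str]] = {}
        for w in sentence_vocab:
            by_domain.setdefault(partition.domain_of(w), []).append(w)
        domains = sorted(by_domain)
        if len(domains) < 2:
            raise ValueError("homophone pairs need words from >= 2 domains")
        capacity = sum(len(v) for v in by_domain.values()) // 2
        if n_pairs > capacity:
            raise ValueError("homophone request exceeds cross-domain capacity")
        pool = {d: list(rng.permutation(ws)) for d, ws in by_domain.items()}
        for p in range(n_pairs):
            d1, d2 = rng.choice(domains, size=2, replace=False)
            a, b = pool[d1].pop(), pool[d2].pop()
            phonetic_id[a] = phonetic_id[b] = f"h{p}"
            boost_words += [a, b]
        # same-domain control words for the non-homophone comparison, recurring
        # as often as the homophones so |delta rate| noise floors match
        for p in range(n_pairs):
            d = domains[int(rng.integers(len(domains)))]
            if len(pool[d]) >= 2:
                boost_words += [pool[d].pop(), pool[d].pop()]

    sentences: list[list[str]] = []
    n_tok = cfg.n_sentences * cfg.sentence_length
    tokens = _deal_tokens(sentence_vocab, n_tok, rng)
    for s in range(cfg.n_sentences):
        sentences.append(tokens[s * cfg.sentence_length : (s + 1) * cfg.sentence_length])

    # ensure homophone/control words recur enough for the pairwise contrasts
    if boost_words and cfg.min_homophone_occurrences > 0:
        from collections import Counter

        counts = Counter(t for sent in sentences for t in sent)
        boost_set = set(boost_words)
        slots = [(s, i) for s, sent in enumerate(sentences)
                 for i in range(len(sent)) if sent[i] not in boost_set]
        slots = [slots[j] for j in rng.permutation(len(slots))]
        for w in boost_words:
            while counts[w] < cfg.min_homophone_occurrences and slots:
                s, i = slots.pop()
                t = sentences[s][i]
                if counts[t] <= 1:  # keep full vocabulary coverage
                    continue
                sentences[s][i] = w
                counts[t] -= 1
                counts[w] += 1

    events: list[WordEvent] = []
    for s, sent in enumerate(sentences):
        for pos, tok in enumerate(sent, start=1):
            events.append(
                WordEvent(tok, phonetic_id[tok], 0.0, "sentence", s, pos,
                          partition.domain_of(tok))
            )

    # --- word lists: shuffled copies of sentences -------------------------
    n_wl = cfg.n_sentences if cfg.n_wordlist_sentences is None else cfg.n_wordlist_sentences
    for s in range(min(n_wl, cfg.n_sentences)):
        shuffled = list(rng.permutation(sentences[s]))
        for pos, tok in enumerate(shuffled, start=1):
            events.append(
                WordEvent(tok, phonetic_id[tok], 0.0, "word_list", s, pos,
                          partition.domain_of(tok))
            )

    # --- nonword blocks ---------------------------------------------------
    nw_counter = 0
    for b in range(cfg.nonword_blocks):
        for pos in range(1, cfg.sentence_length + 1):
            tok = f"nw_{nw_counter}"
            nw_counter += 1
            events.append(
                WordEvent(tok, tok, 0.0, "nonword", cfg.n_sentences + b, pos, None)
            )

    # --- story: partially novel vocabulary --------------------------------
    if cfg.n_story_sentences > 0 and (cfg.story_vocab_new + cfg.story_vocab_shared) > 0:
        new_words = sorted(w for w in partition.words if w.startswith("s"))
        shared = list(rng.choice(sentence_vocab, size=cfg.story_vocab_shared,
                                 replace=False))
        story_vocab = new_words + shared
        story_tokens = _deal_tokens(
            story_vocab, cfg.n_story_sentences * cfg.sentence_length, rng
        )
        for s in range(cfg.n_story_sentences):
            sid = cfg.n_sentences + cfg.nonword_blocks + s
            chunk = story_tokens[s * cfg.sentence_length : (s + 1) * cfg.sentence_length]
            for pos, tok in enumerate(chunk, start=1):
                events.append(
                    WordEvent(tok, phonetic_id[tok], 0.0, "story", sid, pos,
                              partition.domain_of(tok))
                )

    # --- onsets: strictly increasing, ~341 +- 5 ms spacing ----------------
    gaps = np.maximum(
        rng.normal(cfg.inter_onset, cfg.onset_jitter, size=len(events)), 1e-3
    )
    onsets = np.cumsum(gaps)
    for ev, t in zip(events, onsets):
        ev.onset = float(t)
    return events


# ---------------------------------------------------------------------------
# Poisson spiking population
# ---------------------------------------------------------------------------

def simulate_population(
    cfg: GeneratorConfig,
    events: list[WordEvent],
    partition: DomainPartition,
    seed: int | None = None,
    predictability: np.ndarray | None = None,
) -> SpikeData:
    """Draw Poisson spikes for each unit in each word's response window.

    A selective unit fires at baseline + gain for preferred-domain words
    (gain scaled by `context_attenuation` in the word-list condition and,
    when `surprisal_sensitivity` > 0, by the word's predictability). In
    geometry mode the gain instead scales with the positive part of the
    cosine between the word vector and the unit's preferred direction (its
    domain centroid), so tuning follows the embedding geometry. In the
    phonetic-mode control, units respond to a random set of phonetic ids
    rather than to meaning. Nonwords drive a configurable fraction of units
    at an attenuated rate.
    """
    if not events:
        raise ValueError("no events to simulate")
    if predictability is not None:
        predictability = np.asarray(predictability, dtype=float)
        if predictability.shape != (len(events),):
            raise ValueError("predictability must have one entry per event")
    seed = cfg.seed if seed is None else seed
    rng = rng_for(seed, "population")

    n_sel = int(round(cfg.frac_selective * cfg.n_units))
    selective = np.zeros(cfg.n_units, dtype=bool)
    selective[rng.choice(cfg.n_units, size=n_sel, replace=False)] = True
    preferred = np.where(
        selective, rng.integers(1, cfg.n_domains + 1, size=cfg.n_units), 0
    )
    nonword_disc = rng.random(cfg.n_units) < cfg.frac_nonword_discriminating

    all_pids = sorted({ev.phonetic_id for ev in events})
    preferred_pids: dict[int, set[str]] = {}
    if cfg.phonetic_mode:
        n_pref = max(1, len(all_pids) // cfg.n_domains)
        for u in range(cfg.n_units):
            if selective[u]:
                preferred_pids[u] = set(
                    rng.choice(all_pids, size=n_pref, replace=False)
                )

    # per-event tuning drive in [0, 1] for each unit, vectorised over events
    domains = np.array([ev.domain if ev.domain is not None else -1 for ev in events])
    is_wordlist = np.array([ev.condition == "word_list" for ev in events])
    is_nonword = np.array([ev.condition == "nonword" for ev in events])
    beta = cfg.surprisal_sensitivity
    pred_scale = np.ones(len(events))
    if predictability is not None and beta > 0:
        pred_scale = (1.0 - beta) + beta * predictability

    if cfg.geometry_mode:
        word_vecs = np.zeros((len(events), partition.centroids.shape[1]))
        for i, ev in enumerate(events):
            if ev.domain is not None:
                word_vecs[i] = _unit(_lookup_vector(ev.token, partition, events))

    spikes: dict[int, np.ndarray] = {}
    truth: dict[int, dict] = {}
    onsets = np.array([ev.onset for ev in events])
    starts = onsets + cfg.window_lag
    dur = cfg.window_dur
    for u in range(cfg.n_units):
        if not selective[u]:
            drive = np.zeros(len(events))
        elif cfg.phonetic_mode:
            pids = preferred_pids[u]
            drive = np.array([1.0 if ev.phonetic_id in pids else 0.0 for ev in events])
        elif cfg.geometry_mode:
            pref_dir = partition.centroids[preferred[u] - 1]
            drive = np.clip(word_vecs @ pref_dir, 0.0, None)
            drive[is_nonword] = 0.0
        else:
            drive = (domains == preferred[u]).astype(float)
        gain = cfg.tuning_gain * drive * pred_scale
        gain[is_wordlist] *= cfg.context_attenuation
        rate = cfg.baseline_rate + gain
        rate[is_nonword] = cfg.baseline_rate * (
            1.0 - (cfg.nonword_discriminability if nonword_disc[u] else 0.0)
        )
        counts = rng.poisson(rate * dur)
        times = np.concatenate(
            [
                starts[i] + rng.random(c) * dur
                for i, c in enumerate(counts)
                if c > 0
            ]
        ) if counts.sum() else np.empty(0)
        spikes[u] = np.sort(times)
        truth[u] = {
            "selective": bool(selective[u]),
            "preferred_domain": int(preferred[u]) if selective[u] else None,
            "nonword_discriminating": bool(nonword_disc[u]),
        }
    return SpikeData(spikes, truth)


_VEC_CACHE: dict[int, dict[str, np.ndarray]] = {}


def _lookup_vector(token: str, partition: DomainPartition, events) -> np.ndarray:
    # geometry mode needs word vectors; they are attached via attach_vectors()
    cache = _VEC_CACHE.get(id(partition))
    if cache is None or token not in cache:
        raise ValueError(
            "geometry mode requires attach_vectors(partition, table) first"
        )
    return cache[token]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n else v


def attach_vectors(partition: DomainPartition, table: EmbeddingTable) -> None:
    """Register word vectors for geometry-mode simulation."""
    _VEC_CACHE[id(partition)] = {w: table.vector(w) for w in partition.words}


def generate_session(cfg: GeneratorConfig) -> SyntheticSession:
    """Generate a complete session (space, stimuli, spikes) from one config."""
    table, partition = generate_embedding_space(cfg)
    events = generate_stimuli(cfg, partition)
    if cfg.geometry_mode:
        attach_vectors(partition, table)
    spikes = simulate_population(cfg, events, partition)
    return SyntheticSession(table, partition, events, spikes, cfg)


def generate_sessions(cfg: GeneratorConfig, n_sessions: int) -> list[SyntheticSession]:
    """Independent sessions differing only in their derived seeds."""
    return [
        generate_session(replace(cfg, seed=int(rng_for(cfg.seed, "session", s).integers(2**31 - 1))))
        for s in range(n_sessions)
    ]


# ---------------------------------------------------------------------------
# Event (de)serialisation
# ---------------------------------------------------------------------------

_EVENT_COLS = ["token", "phonetic_id", "onset", "condition", "sentence_id",
               "position", "domain"]


def events_to_frame(events: list[WordEvent]) -> pd.DataFrame:
    df = pd.DataFrame([[getattr(ev, c) for c in _EVENT_COLS] for ev in events],
                      columns=_EVENT_COLS)
    return df


def frame_to_events(df: pd.DataFrame) -> list[WordEvent]:
    out = []
    for row in df.itertuples(index=False):
        d = row.domain
        domain = None if pd.isna(d) else int(d)
        out.append(WordEvent(str(row.token), str(row.phonetic_id), float(row.onset),
                             str(row.condition), int(row.sentence_id),
                             int(row.position), domain))
    return out
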