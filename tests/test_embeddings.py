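"""Embedding I/O, spherical clustering, silhouette selection, purity, d'."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurosem as ns
from neurosem.embeddings import (
    EmbeddingFormatError,
    _normalize_rows,
    _spherical_kmeans_labels,
    kmeans_objective,
)


def _table(words, vecs):
    return ns.EmbeddingTable(words, np.asarray(vecs, dtype=float))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "emb.txt"
        p.write_text("2 3\ndog 1 0 0\ncat 0 1 0\n")
        t = ns.read_embeddings(p)
        assert t.words == ["dog", "cat"] and t.dim == 3
        np.testing.assert_allclose(t.vector("cat"), [0, 1, 0])

    def test_roundtrip(self, tmp_path, rng):
        vecs = rng.normal(size=(7, 5))
        t = _table([f"w{i}" for i in range(7)], vecs)
        ns.write_embeddings(t, tmp_path / "e.txt")
        back = ns.read_embeddings(tmp_path / "e.txt")
        np.testing.assert_allclose(back.vectors, t.vectors, atol=1e-6)

    def test_duplicate_word_dialects(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("2 2\na 1 0\na 0 1\n")
        with pytest.raises(EmbeddingFormatError):
            ns.read_embeddings(p)
        t = ns.read_embeddings(p, on_duplicate="last")
        np.testing.assert_allclose(t.vector("a"), [0, 1])

    def test_dimension_mismatch_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("2 3\ndog 1 0 0\ncat 0 1\n")
        with pytest.raises(EmbeddingFormatError, match="line 3"):
            ns.read_embeddings(p)

    def test_vocab_filter_case_insensitive(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("3 2\nDog 1 0\ncat 0 1\nfox 1 1\n")
        t = ns.read_embeddings(p, vocab={"DOG", "cat"})
        assert set(t.words) == {"dog", "cat"}


class TestFilterFrequentWords:
    def test_threshold(self):
        t = _table(["a", "dog"], [[1, 0], [0, 1]])
        kept = ns.filter_frequent_words(t, {"a": 3.0, "dog": 1.0}, 2.5)
        assert kept.words == ["dog"]

    def test_infinite_threshold_is_identity(self):
        t = _table(["a", "b"], [[1, 0], [0, 1]])
        assert ns.filter_frequent_words(t, {"a": 1.0, "b": 2.0}, np.inf).words == t.words

    def test_zipf_percentile_count(self, rng):
        n = 50
        scores = {f"w{i}": float(np.log(1.0 / (i + 1))) for i in range(n)}
        t = _table(list(scores), rng.normal(size=(n, 4)))
        thr = float(np.percentile(list(scores.values()), 90))
        kept = ns.filter_frequent_words(t, scores, thr)
        # oracle: count by sorting
        expected = sum(1 for s in scores.values() if s <= thr)
        assert len(kept) == expected

    def test_all_filtered_errors(self):
        t = _table(["a"], [[1.0, 0.0]])
        with pytest.raises(ValueError, match="all words filtered"):
            ns.filter_frequent_words(t, {"a": 9.0}, 1.0)


# ---------------------------------------------------------------------------
# Spherical k-means
# ---------------------------------------------------------------------------

class TestSphericalKMeans:
    def test_antipodal_bundles_recovered(self, rng):
        a = np.array([1.0, 0.0]) + rng.normal(scale=0.01, size=(6, 2))
        b = np.array([-1.0, 0.0]) + rng.normal(scale=0.01, size=(6, 2))
        t = _table([f"w{i}" for i in range(12)], np.vstack([a, b]))
        part = ns.spherical_kmeans(t, 2, seed=0)
        labels = [part.domain_of(w) for w in t.words]
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_k_bounds(self, rng):
        t = _table(["a", "b", "c"], rng.normal(size=(3, 3)))
        with pytest.raises(ValueError):
            ns.spherical_kmeans(t, 1)
        with pytest.raises(ValueError):
            ns.spherical_kmeans(t, 4)

    def test_matches_exhaustive_assignment_oracle(self, rng):
        # 12 points in 3 planted clusters: enumerate all centroid-consistent
        # label assignments and take the best cosine objective
        centers = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        pts = np.vstack([c + rng.normal(scale=0.05, size=(4, 3)) for c in centers])
        t = _table([f"w{i}" for i in range(12)], pts)
        part = ns.spherical_kmeans(t, 3, seed=2)
        got = kmeans_objective(t, part)
        unit = _normalize_rows(pts)
        best = -np.inf
        for labels in itertools.product(range(3), repeat=12):
            if len(set(labels)) < 3:
                continue
            obj = 0.0
            for j in range(3):
                grp = unit[np.array(labels) == j]
                m = grp.mean(axis=0)
                obj += (grp @ (m / np.linalg.norm(m))).sum()
            best = max(best, obj)
        assert got == pytest.approx(best, rel=1e-9)

    def test_objective_nondecreasing_over_iterations(self, rng):
        pts = rng.normal(size=(40, 6))
        unit = _normalize_rows(pts)
        # re-run Lloyd manually, tracking the objective at each step
        gen = np.random.default_rng(5)
        centroids = unit[gen.choice(40, size=4, replace=False)]
        prev = -np.inf
        for _ in range(25):
            sims = unit @ centroids.T
            labels = np.argmax(sims, axis=1)
            obj = sims[np.arange(40), labels].sum()
            assert obj >= prev - 1e-9
            prev = obj
            for j in range(4):
                if np.any(labels == j):
                    m = unit[labels == j].mean(axis=0)
                    centroids[j] = m / np.linalg.norm(m)


class TestSelectClusterCount:
    def test_recovers_planted_nine(self, default_session):
        k_star, crit = ns.select_cluster_count(
            default_session.table, (5, 20), n_repeats=3, seed=4
        )
        assert k_star == 9
        assert crit.attrs["k_mode"] == 9

    def test_isotropic_cloud_flagged_weak(self, rng):
        t = _table([f"w{i}" for i in range(60)], rng.normal(size=(60, 8)))
        _, crit = ns.select_cluster_count(t, (2, 5), n_repeats=3, seed=0)
        assert crit.attrs["weak_separation"]
        assert crit["mean_silhouette"].max() < 0.25

    def test_silhouette_matches_brute_force(self, rng):
        # tiny 2-cluster instance: recompute mean silhouette per point by hand
        pts = np.vstack([
            np.array([1.0, 0.2]) + rng.normal(scale=0.05, size=(5, 2)),
            np.array([-1.0, 0.1]) + rng.normal(scale=0.05, size=(5, 2)),
        ])
        t = _table([f"w{i}" for i in range(10)], pts)
        unit = _normalize_rows(pts)
        labels, _ = _spherical_kmeans_labels(unit, 2, np.random.default_rng(0))
        dist = 1.0 - unit @ unit.T
        np.fill_diagonal(dist, 0.0)
        sils = []
        for i in range(10):
            same = (labels == labels[i]) & (np.arange(10) != i)
            a = dist[i, same].mean()
            b = min(dist[i, labels == l].mean() for l in set(labels) - {labels[i]})
            sils.append((b - a) / max(a, b))
        from sklearn.metrics import silhouette_score
        got = silhouette_score(np.clip(dist, 0, None), labels, metric="precomputed")
        assert got == pytest.approx(np.mean(sils), abs=1e-9)

    def test_krange_truncated_with_warning(self, rng):
        t = _table([f"w{i}" for i in range(8)], rng.normal(size=(8, 3)))
        with pytest.warns(UserWarning, match="truncat"):
            ns.select_cluster_count(t, (2, 10), n_repeats=2, seed=0)


# ---------------------------------------------------------------------------
# Purity and d'
# ---------------------------------------------------------------------------

def _partition(groups):
    assignment = {w: i + 1 for i, grp in enumerate(groups) for w in grp}
    k = len(groups)
    eye = np.eye(max(k, 2))[:k]
    return ns.DomainPartition(assignment, eye)


class TestPurity:
    def test_identity_is_one(self):
        p = _partition([["a", "b"], ["c", "d"]])
        assert ns.purity(p, p) == 1.0

    def test_worked_example(self):
        new = _partition([["a", "b", "c"], ["d", "e", "f"]])
        ref = _partition([["a", "b", "d"], ["c", "e", "f"]])
        assert ns.purity(new, ref) == pytest.approx(4 / 6)

    def test_single_cluster_vs_singletons(self):
        words = list("abcdef")
        new = _partition([words, []])  # everything in one cluster
        ref = _partition([[w] for w in words])
        assert ns.purity(new, ref) == pytest.approx(1 / 6)

    def test_word_set_mismatch_errors(self):
        with pytest.raises(ValueError, match="symmetric difference"):
            ns.purity(_partition([["a"], ["b"]]), _partition([["a"], ["c"]]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 2), min_size=6, max_size=12),
           st.permutations(list(range(3))))
    def test_label_permutation_invariance(self, labels, perm):
        """Purity only counts overlaps, so renaming clusters cannot change it."""
        words = [f"w{i}" for i in range(len(labels))]
        ref = _partition([[w for w, l in zip(words, labels) if l == j] or []
                          for j in range(3)])
        new_groups = [[w for w, l in zip(words, labels) if perm[l] == j] or []
                      for j in range(3)]
        base = ns.purity(_partition([words[::2], words[1::2]]), ref)
        permuted_ref = _partition(new_groups)
        val = ns.purity(_partition([words[::2], words[1::2]]), permuted_ref)
        assert val == pytest.approx(base)
        assert 0 < val <= 1

    def test_monotone_under_correction(self):
        ref = _partition([["a", "b", "c"], ["d", "e", "f"]])
        worse = _partition([["a", "b", "d"], ["c", "e", "f"]])
        better = _partition([["a", "b", "c"], ["d", "e", "f"]])
        assert ns.purity(worse, ref) <= ns.purity(better, ref)


class TestDPrime:
    def test_matches_direct_formula(self, rng):
        """d' for one domain equals the formula evaluated over scipy cosine
        distances collected pair by pair."""
        from scipy.spatial.distance import cosine

        vecs = np.vstack([
            np.array([1.0, 0.1, 0]) + rng.normal(scale=0.1, size=(4, 3)),
            np.array([0, 1.0, 0.1]) + rng.normal(scale=0.1, size=(4, 3)),
        ])
        words = [f"w{i}" for i in range(8)]
        t = _table(words, vecs)
        part = _partition([words[:4], words[4:]])
        got = ns.dprime_separability(part, t)
        unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        within = [cosine(unit[i], unit[j]) for i in range(4) for j in range(i + 1, 4)]
        between = [cosine(unit[i], unit[j]) for i in range(4) for j in range(4, 8)]
        within, between = np.array(within), np.array(between)
        pooled = (within.var(ddof=1) + between.var(ddof=1)) / 2
        expected = (between.mean() - within.mean()) / np.sqrt(pooled)
        assert got[1] == pytest.approx(expected, rel=1e-9)
        assert got[1] > 0  # convention: positive for tight clusters

    def test_planted_domains_all_positive(self, small_session):
        d = ns.dprime_separability(small_session.partition, small_session.table)
        assert all(v > 0 for v in d.values())

    def test_identical_distributions_near_zero(self, rng):
        # one isotropic cloud split arbitrarily into two "domains"
        vecs = rng.normal(size=(40, 6))
        t = _table([f"w{i}" for i in range(40)], vecs)
        part = _partition([[f"w{i}" for i in range(20)],
                           [f"w{i}" for i in range(20, 40)]])
        d = ns.dprime_separability(part, t)
        assert all(abs(v) < 0.5 for v in d.values())
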