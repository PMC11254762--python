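"""Word-embedding I/O, spherical clustering, and cluster-quality diagnostics.

Words are represented as unit-norm vectors on the sphere; semantic domains are
clusters of these vectors under cosine distance. Domain discovery uses a
Lloyd-style spherical k-means (assign by maximal cosine similarity, recompute
centroids as normalised means) with the cluster count chosen by a repeated
silhouette criterion. Purity and d' quantify how well a re-derived clustering
matches a reference partition and how separable the domains are.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from ._rng import rng_for

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingTable",
    "DomainPartition",
    "read_embeddings",
    "write_embeddings",
    "filter_frequent_words",
    "spherical_kmeans",
    "select_cluster_count",
    "purity",
    "dprime_separability",
]


class EmbeddingFormatError(ValueError):
    """Raised on malformed word2vec text input."""


@dataclass
class EmbeddingTable:
    """Vocabulary of d-dimensional word vectors.

    Vectors are stored as given; `normalized()` returns a unit-L2-norm copy.
    Words are unique, lowercase tokens.
    """

    words: list[str]
    vectors: np.ndarray  # (n_words, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.words):
            raise ValueError("vectors must be (n_words, dim)")
        if len(set(self.words)) != len(self.words):
            raise ValueError("duplicate words in embedding table")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm embedding vector")
        self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    def index(self, word: str) -> int:
        return self._index[word]

    def normalized(self) -> "EmbeddingTable":
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        return EmbeddingTable(list(self.words), self.vectors / norms)

    def subset(self, words) -> "EmbeddingTable":
        words = list(words)
        idx = [self._index[w] for w in words]
        return EmbeddingTable(words, self.vectors[idx])


@dataclass
class DomainPartition:
    """Assignment of every vocabulary word to exactly one semantic domain.

    Domains are labelled 1..k; `centroids` holds one unit vector per domain.
    """

    assignment: dict[str, int]
    centroids: np.ndarray  # (k, dim)
    labels: dict[int, str] | None = None
    k: int = field(init=False)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.k = self.centroids.shape[0]
        if self.k < 2:
            raise ValueError("a partition needs k >= 2 domains")
        doms = set(self.assignment.values())
        if not doms <= set(range(1, self.k + 1)):
            raise ValueError("domain labels must lie in 1..k")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("centroids must be unit-norm")

    @property
    def words(self) -> list[str]:
        return list(self.assignment)

    def domain_of(self, word: str) -> int:
        return self.assignment[word]

    def members(self, domain: int) -> list[str]:
        return [w for w, d in self.assignment.items() if d == domain]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"word": list(self.assignment), "domain": list(self.assignment.values())}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O: word2vec text format ("n d" header, then "word v1 ... vd" per line)
# ---------------------------------------------------------------------------

def read_embeddings(path, vocab=None, on_duplicate: str = "error") -> EmbeddingTable:
    """Read a word2vec-text embedding file.

    Parameters
    ----------
    path : str or Path
        File with header line "n d" followed by one "word v1 ... vd" line per
        word.
    vocab : iterable of str, optional
        If given, only words in this set are loaded (matched
        case-insensitively); missing words are logged.
    on_duplicate : {"error", "last"}
        Whether a repeated word is a parse error or silently overwritten by
        its last occurrence (logged either way).
    """
    wanted = {w.lower() for w in vocab} if vocab is not None else None
    words: list[str] = []
    vecs: list[np.ndarray] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError("line 1: expected header 'n d'")
        try:
            n_decl, dim = int(header[0]), int(header[1])
        except ValueError as e:
            raise EmbeddingFormatError(f"line 1: non-integer header: {e}") from e
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            word = parts[0].lower()
            if len(parts) - 1 != dim:
                raise EmbeddingFormatError(
                    f"line {lineno}: expected {dim} values, got {len(parts) - 1}"
                )
            if wanted is not None and word not in wanted:
                continue
            try:
                vec = np.array(parts[1:], dtype=float)
            except ValueError as e:
                raise EmbeddingFormatError(f"line {lineno}: bad float: {e}") from e
            if word in seen:
                logger.warning("duplicate word %r at line %d", word, lineno)
                if on_duplicate == "error":
                    raise EmbeddingFormatError(f"line {lineno}: duplicate word {word!r}")
                vecs[seen[word]] = vec
                continue
            seen[word] = len(words)
            words.append(word)
            vecs.append(vec)
    if wanted is not None:
        missing = sorted(wanted - set(words))
        if missing:
            logger.info("%d vocabulary words absent from embedding file", len(missing))
    if n_decl != len(seen) and wanted is None:
        logger.warning("header declared %d words, parsed %d", n_decl, len(words))
    return EmbeddingTable(words, np.vstack(vecs))


def write_embeddings(table: EmbeddingTable, path) -> None:
    """Write a table in word2vec text format (round-trips with read_embeddings)."""
    with open(path, "w") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for w, v in zip(table.words, table.vectors):
            fh.write(w + " " + " ".join(repr(float(x)) for x in v) + "\n")


def filter_frequent_words(
    table: EmbeddingTable,
    freq: dict[str, float],
    threshold: float,
    drop_above: bool = True,
) -> EmbeddingTable:
    """Remove high-frequency function words before clustering.

    Words whose frequency score exceeds `threshold` are dropped (or fall below
    it, with `drop_above=False`); words missing from `freq` are kept and
    logged.
    """
    kept = []
    for w in table.words:
        if w not in freq:
            logger.debug("no frequency score for %r; kept", w)
            kept.append(w)
            continue
        s = freq[w]
        drop = s > threshold if drop_above else s < threshold
        if not drop:
            kept.append(w)
    if not kept:
        raise ValueError("all words filtered")
    return table.subset(kept)


# ---------------------------------------------------------------------------
# Spherical k-means + silhouette model selection
# ---------------------------------------------------------------------------

def _normalize_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _plusplus_init(
    unit_vecs: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding under cosine distance (squared-distance sampling)."""
    n = unit_vecs.shape[0]
    centroids = np.empty((k, unit_vecs.shape[1]))
    centroids[0] = unit_vecs[rng.integers(n)]
    d2 = np.clip(1.0 - unit_vecs @ centroids[0], 0.0, None) ** 2
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centroids[j] = unit_vecs[rng.choice(n, p=probs)]
        d2 = np.minimum(
            d2, np.clip(1.0 - unit_vecs @ centroids[j], 0.0, None) ** 2)
    return centroids


def _spherical_kmeans_labels(
    unit_vecs: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 100,
    n_init: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Best of `n_init` restarts of Lloyd iteration on the unit sphere,
    ranked by the summed cosine similarity to assigned centroids; returns
    (labels 0..k-1, centroids)."""
    best = None
    for _ in range(n_init):
        labels, centroids = _spherical_kmeans_once(unit_vecs, k, rng, max_iter)
        obj = (unit_vecs * centroids[labels]).sum()
        if best is None or obj > best[0]:
            best = (obj, labels, centroids)
    return best[1], best[2]


def _spherical_kmeans_once(
    unit_vecs: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    n = unit_vecs.shape[0]
    centroids = _plusplus_init(unit_vecs, k, rng)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        sims = unit_vecs @ centroids.T
        new_labels = np.argmax(sims, axis=1)
        # re-seed empty clusters with the points farthest from their centroid
        assigned_sim = sims[np.arange(n), new_labels]
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(np.argmin(assigned_sim))
                new_labels[far] = j
                assigned_sim[far] = np.inf
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            mean = unit_vecs[labels == j].mean(axis=0)
            nrm = np.linalg.norm(mean)
            if nrm > 0:
                centroids[j] = mean / nrm
    return labels, centroids


def spherical_kmeans(table: EmbeddingTable, k: int, seed: int = 0) -> DomainPartition:
    """Cluster word vectors into k domains by cosine similarity.

    Deterministic for a fixed seed; empty clusters are re-seeded from the
    point farthest from its current centroid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(table):
        raise ValueError(f"k={k} exceeds vocabulary size {len(table)}")
    unit = _normalize_rows(table.vectors)
    labels, centroids = _spherical_kmeans_labels(unit, k, rng_for(seed, "skmeans", k))
    assignment = {w: int(l) + 1 for w, l in zip(table.words, labels)}
    return DomainPartition(assignment, centroids)


def kmeans_objective(table: EmbeddingTable, partition: DomainPartition) -> float:
    """Sum of cosine similarities of each word to its assigned centroid."""
    unit = _normalize_rows(table.vectors)
    total = 0.0
    for i, w in enumerate(table.words):
        total += float(unit[i] @ partition.centroids[partition.domain_of(w) - 1])
    return total


def select_cluster_count(
    table: EmbeddingTable,
    k_range: tuple[int, int] = (5, 20),
    n_repeats: int = 100,
    seed: int = 0,
    weak_floor: float = 0.25,  # isotropic clouds reach ~0.2 under cosine
) -> tuple[int, pd.DataFrame]:
    """Choose the domain count by a repeated mean-silhouette criterion.

    For each repeat, the vocabulary is clustered at every k in `k_range` with
    pseudorandom seeding and the mean silhouette under cosine distance is
    recorded. The selected k maximises the average criterion (ties go to the
    smaller k, for parsimony); the per-repeat argmax mode is reported
    alongside.

    Returns (k_star, table with columns k / mean_silhouette / modal_count and
    attrs {"k_star", "k_mode", "weak_separation"}).
    """
    lo, hi = k_range
    if hi >= len(table):
        warnings.warn(f"k_range upper {hi} >= vocabulary size; truncating")
        hi = len(table) - 1
    if lo < 2:
        raise ValueError("k_range lower bound must be >= 2")
    ks = np.arange(lo, hi + 1)
    unit = _normalize_rows(table.vectors)
    # cosine distances, reused by every silhouette evaluation
    dist = np.clip(1.0 - unit @ unit.T, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    sil = np.empty((n_repeats, len(ks)))
    for r in range(n_repeats):
        rng = rng_for(seed, "select_k", r)
        for j, k in enumerate(ks):
            labels, _ = _spherical_kmeans_labels(unit, int(k), rng)
            sil[r, j] = silhouette_score(dist, labels, metric="precomputed")
    mean_sil = sil.mean(axis=0)
    k_star = int(ks[np.argmax(mean_sil)])  # argmax returns first (smallest) tie
    per_repeat_best = ks[np.argmax(sil, axis=1)]
    modal_counts = np.array([(per_repeat_best == k).sum() for k in ks])
    k_mode = int(ks[np.argmax(modal_counts)])
    out = pd.DataFrame({"k": ks, "mean_silhouette": mean_sil, "modal_count": modal_counts})
    out.attrs["k_star"] = k_star
    out.attrs["k_mode"] = k_mode
    out.attrs["weak_separation"] = bool(mean_sil.max() < weak_floor)
    if out.attrs["weak_separation"]:
        warnings.warn("weak separation: max mean silhouette below floor")
    return k_star, out


# ---------------------------------------------------------------------------
# Cluster quality: purity and d'
# ---------------------------------------------------------------------------

def purity(new: DomainPartition, ref: DomainPartition) -> float:
    """Fraction of words a re-derived clustering assigns to the best-matched
    reference cluster: (1/n) * sum_i max_j |omega_i ∩ c_j|.
    """
    new_words, ref_words = set(new.assignment), set(ref.assignment)
    if new_words != ref_words:
        diff = sorted(new_words ^ ref_words)
        raise ValueError(f"word sets differ; symmetric difference: {diff}")
    n = len(new_words)
    total = 0
    for i in range(1, new.k + 1):
        omega = set(new.members(i))
        if not omega:
            continue
        best = max(
            len(omega & set(ref.members(j))) for j in range(1, ref.k + 1)
        )
        total += best
    return total / n


def dprime_separability(
    partition: DomainPartition, table: EmbeddingTable
) -> dict[int, float]:
    """Per-domain d' between within-domain and between-domain cosine distances.

    Positive when within-domain distances are smaller (tighter cluster):
    d' = (mu_between - mu_within) / sqrt((s_within^2 + s_between^2) / 2).
    """
    unit = _normalize_rows(table.subset(partition.words).vectors)
    words = partition.words
    idx = {w: i for i, w in enumerate(words)}
    dist = np.clip(1.0 - unit @ unit.T, 0.0, None)
    out: dict[int, float] = {}
    for d in range(1, partition.k + 1):
        members = [idx[w] for w in partition.members(d)]
        if len(members) < 2:
            warnings.warn(f"domain {d} has <2 words; d' undefined")
            out[d] = float("nan")
            continue
        others = [i for i in range(len(words)) if i not in set(members)]
        m = np.array(members)
        within = squareform(dist[np.ix_(m, m)], checks=False)
        between = dist[np.ix_(m, np.array(others))].ravel()
        pooled = (within.var(ddof=1) + between.var(ddof=1)) / 2.0
        if pooled == 0:
            warnings.warn(f"domain {d}: zero pooled variance; d' is NaN")
            out[d] = float("nan")
            continue
        out[d] = float((between.mean() - within.mean()) / np.sqrt(pooled))
    return out
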