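"""The neuronal-semantic space.

Each unit's normalised (z-scored) mean firing rate per word F_{i,w} is
modelled as a linear function of the word's embedding vector,
F_{i,w} = v_w theta_i + eps_i, fit by ridge regression (lambda = 1e-4 by
default) through the normal equations. Stacking the per-unit weight vectors
gives a units x dim matrix whose principal components (over the neuronal
dimension, preserving embedding dimension) span a low-dimensional semantic
space; projecting word embeddings on these components places every word in
it. Correlating pairwise distances — projection space vs embedding space,
and |delta population rate| vs embedding or cophenetic (single-linkage merge
height) distance — quantifies how much of the semantic geometry, including
its hierarchy, the population carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from ._rng import rng_for
from .alignment import ResponseMatrix
from .embeddings import EmbeddingTable

__all__ = [
    "SemanticSpace",
    "fit_embedding_regression",
    "pca_space",
    "distance_correlation",
    "rate_distance_correlation",
    "cophenetic_hierarchy",
    "dendrogram_to_newick",
]


@dataclass
class SemanticSpace:
    theta: np.ndarray  # (n_units, dim) ridge weights
    pcs: np.ndarray  # (n_pc, dim)
    explained_variance: np.ndarray  # fraction per PC, non-increasing
    projections: pd.DataFrame  # words x n_pc
    ridge_lambda: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite regression weights")
        ev = self.explained_variance
        if np.any(np.diff(ev) > 1e-12) or ev.sum() > 1 + 1e-9:
            raise ValueError("explained variance must be non-increasing, sum <= 1")


def _word_mean_rates(matrix: ResponseMatrix, table: EmbeddingTable):
    """Per-word mean normalised rate for words present in both matrix and
    table; words with no embedding (e.g. nonwords) or no events are dropped."""
    if not matrix.zscored:
        matrix = matrix.zscore()
    means = matrix.word_means()
    words = [w for w in means.columns if w in table]
    dropped = [w for w in means.columns if w not in table]
    if dropped:
        warnings.warn(f"{len(dropped)} tokens lack embeddings and were dropped")
    return words, means[words].to_numpy()  # (n_units, n_words)


def fit_embedding_regression(
    matrix: ResponseMatrix,
    table: EmbeddingTable,
    ridge_lambda: float = 1e-4,
) -> tuple[np.ndarray, list[str]]:
    """Per-unit ridge regression of word responses onto embedding vectors.

    Solves (V^T V + lambda I) theta_i = V^T F_i for every unit via the normal
    equations, where V stacks the embedding vectors of all words with events
    and F_i is unit i's mean z-scored rate per word. Returns (theta with one
    row per unit, the word order used).
    """
    words, F = _word_mean_rates(matrix, table)
    if len(words) < 2:
        raise ValueError("need at least 2 embedded words with responses")
    V = np.vstack([table.vector(w) for w in words])  # (n_words, dim)
    A = V.T @ V + ridge_lambda * np.eye(V.shape[1])
    theta = np.linalg.solve(A, V.T @ F.T).T  # (n_units, dim)
    return theta, words


def pca_space(
    theta: np.ndarray,
    table: EmbeddingTable,
    n_pc: int = 5,
    ridge_lambda: float = 1e-4,
    words: list[str] | None = None,
) -> SemanticSpace:
    """PCA of the stacked weights along the neuronal dimension.

    Units are samples and embedding dimensions features, so each component
    is a 300-dimensional direction; word embeddings projected on the
    components give each word's coordinates in the reduced space.
    """
    theta = np.asarray(theta, dtype=float)
    max_pc = min(theta.shape)
    rank = np.linalg.matrix_rank(theta - theta.mean(axis=0))
    if n_pc > rank:
        warnings.warn(f"n_pc={n_pc} exceeds rank {rank}; truncated")
        n_pc = max(1, rank)
    n_pc = min(n_pc, max_pc)
    pca = PCA(n_components=n_pc)
    pca.fit(theta)
    if words is None:
        words = list(table.words)
    vecs = np.vstack([table.vector(w) for w in words])
    proj = vecs @ pca.components_.T
    projections = pd.DataFrame(proj, index=words,
                               columns=[f"pc{i+1}" for i in range(n_pc)])
    return SemanticSpace(theta, pca.components_, pca.explained_variance_ratio_,
                         projections, ridge_lambda)


def _pair_cosine(x: np.ndarray) -> np.ndarray:
    return pdist(x, metric="cosine")


def distance_correlation(
    space: SemanticSpace,
    table: EmbeddingTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pearson r between pairwise cosine distances of word projections and of
    the original embeddings, over all unordered word pairs; permutation p by
    shuffling word identity in the projection space.
    """
    words = list(space.projections.index)
    if len(words) < 3:
        raise ValueError("need at least 3 words")
    P = space.projections.to_numpy()
    V = np.vstack([table.vector(w) for w in words])
    dp, dv = _pair_cosine(P), _pair_cosine(V)
    r = float(np.corrcoef(dp, dv)[0, 1])
    rng = rng_for(seed, "distcorr")
    count = 0
    n = len(words)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r0 = np.corrcoef(_pair_cosine(P[perm]), dv)[0, 1]
        if abs(r0) >= abs(r):
            count += 1
    return r, max(count / n_perm, 1.0 / n_perm)


def _binned_r(dist: np.ndarray, delta: np.ndarray, bins: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Percentile-bin `dist`, average `delta` per bin, Pearson r over bins.

    Empty bins (duplicate quantile edges) are merged with neighbours.
    """
    edges = np.unique(np.quantile(dist, np.linspace(0, 1, bins + 1)))
    if len(edges) - 1 < bins:
        warnings.warn("duplicate quantile edges; bins merged")
    idx = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            xs.append(dist[m].mean())
            ys.append(delta[m].mean())
    xs, ys = np.asarray(xs), np.asarray(ys)
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, xs, ys


def rate_distance_correlation(
    matrix: ResponseMatrix,
    table: EmbeddingTable,
    bins: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Binned correlation between embedding distance and |delta rate| per pair.

    For every unordered word pair: cosine distance between embeddings vs the
    absolute difference in population-averaged normalised rate. Distances are
    percentile-binned (default 100 bins) and the Pearson r computed on bin
    means, with a one-sided permutation p (shuffling which rate belongs to
    which word).
    """
    words, F = _word_mean_rates(matrix, table)
    pop = F.mean(axis=0)  # population-average normalised rate per word
    V = np.vstack([table.vector(w) for w in words])
    dv = _pair_cosine(V)
    dr = pdist(pop[:, None], metric="cityblock")  # |delta rate|
    r, xs, ys = _binned_r(dv, dr, bins)
    rng = rng_for(seed, "ratecorr")
    count = 0
    for _ in range(n_perm):
        perm_dr = pdist(pop[rng.permutation(len(pop))][:, None], metric="cityblock")
        r0, _, _ = _binned_r(dv, perm_dr, bins)
        if r0 >= r:  # one-sided: positive association
            count += 1
    return {"r": r, "p": max(count / n_perm, 1.0 / n_perm),
            "bin_distance": xs, "bin_delta_rate": ys, "n_pairs": len(dv)}


def cophenetic_hierarchy(
    table: EmbeddingTable,
    matrix: ResponseMatrix,
    bins: int = 100,
    session_matrices: list[ResponseMatrix] | None = None,
    session_bins: int = 200,
    iqr_factor: float = 2.5,
) -> dict:
    """Single-linkage hierarchy of word embeddings vs neuronal activity.

    Builds the nearest-neighbour merge tree over cosine distances in the
    embedding space (words in lexicographic order for deterministic ties),
    takes the cophenetic distance of every word pair, and correlates the
    binned cophenetic distances with |delta population rate|. When per-session
    matrices are given, a per-session r distribution is computed with finer
    binning and 2.5 x IQR outlier exclusion.
    """
    words, F = _word_mean_rates(matrix, table)
    order = np.argsort(words)
    words = [words[i] for i in order]
    F = F[:, order]
    V = np.vstack([table.vector(w) for w in words])
    dv = _pair_cosine(V)
    Z = linkage(dv, method="single")
    coph = cophenet(Z)
    pop = F.mean(axis=0)
    dr = pdist(pop[:, None], metric="cityblock")
    r, xs, ys = _binned_r(coph, dr, bins)
    out = {"linkage": Z, "words": words, "cophenetic": coph, "r": r,
           "bin_cophenetic": xs, "bin_delta_rate": ys}
    if session_matrices is not None:
        rs = []
        for m in session_matrices:
            w_s, F_s = _word_mean_rates(m, table)
            common = sorted(set(w_s) & set(words))
            if len(common) < 10:
                continue
            iw = {w: i for i, w in enumerate(words)}
            sel = np.array([iw[w] for w in common])
            sub_coph = _condensed_subset(coph, len(words), sel)
            pop_s = F_s[:, [w_s.index(w) for w in common]].mean(axis=0)
            dr_s = pdist(pop_s[:, None], metric="cityblock")
            q1, q3 = np.percentile(dr_s, [25, 75])
            keep = (dr_s >= q1 - iqr_factor * (q3 - q1)) & (
                dr_s <= q3 + iqr_factor * (q3 - q1))
            r_s, _, _ = _binned_r(sub_coph[keep], dr_s[keep],
                                  min(session_bins, keep.sum()))
            rs.append(r_s)
        out["session_r"] = np.asarray(rs)
    return out


def _condensed_subset(condensed: np.ndarray, n: int, idx: np.ndarray) -> np.ndarray:
    """Rows/cols subset of a condensed distance matrix."""
    from scipy.spatial.distance import squareform
    full = squareform(condensed)
    return squareform(full[np.ix_(idx, idx)], checks=False)


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree.

    Branch lengths are merge-height increments, so leaf-to-root path length
    equals the final merge height.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + k
        nodes[node] = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        heights[node] = h
    return nodes[n + len(Z) - 1] + ";"
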