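"""Population decoding of semantic domains from word-aligned firing rates.

Per-word domain labels are predicted from the concatenated rates of the
candidate (typically semantically selective) units with linear max-margin
classifiers (C = 1, balanced class weights), trained on random 60% splits of
the *sentences* and evaluated class-balanced on the held-out words, so chance
is exactly 1/k (11% for nine domains). Significance comes from an empirical
permutation null built by shuffling the domain labels and repeating the whole
procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._rng import child_seed, rng_for
from .alignment import ResponseMatrix
from .embeddings import DomainPartition, EmbeddingTable, spherical_kmeans

__all__ = [
    "DecoderConfig",
    "DecodingResult",
    "decode_domains",
    "permutation_null",
    "generalize_across_materials",
    "improvement_surface",
]


@dataclass
class DecoderConfig:
    """Classifier and resampling settings for domain decoding."""

    C: float = 1.0
    kernel: str = "linear"
    class_weight: str = "balanced"
    train_fraction: float = 0.6
    n_iterations: int = 1000
    n_permutations: int = 1000
    multiclass: str = "ovr"  # "ovr" (default) or "ovo"
    standardize: bool = True  # fit scaler on the training split only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    def make_classifier(self):
        svc = SVC(kernel=self.kernel, C=self.C, class_weight=self.class_weight)
        return svc if self.multiclass == "ovo" else OneVsRestClassifier(svc)


@dataclass
class DecodingResult:
    """Accuracy distribution over train/test iterations plus a null."""

    accuracies: np.ndarray  # balanced accuracy per iteration
    raw_accuracies: np.ndarray
    null: np.ndarray | None = None
    p_value: float | None = None
    confusion: np.ndarray | None = None  # summed over iterations
    domains: list[int] | None = None
    per_event_tested: np.ndarray | None = None  # times each event was held out
    per_event_correct: np.ndarray | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0

    def per_event_rate(self) -> np.ndarray:
        """Per-event fraction correct across held-out appearances (NaN if never
        tested)."""
        with np.errstate(invalid="ignore"):
            return self.per_event_correct / self.per_event_tested

    def summary(self) -> dict:
        out = {"mean_accuracy": self.mean_accuracy, "sd_accuracy": self.sd_accuracy,
               "n_iterations": len(self.accuracies),
               "mean_raw_accuracy": float(self.raw_accuracies.mean())}
        if self.p_value is not None:
            out["p_value"] = self.p_value
            out["null_mean"] = float(self.null.mean())
        return out


def _features_labels(matrix: ResponseMatrix, units):
    sub = matrix.subset_units(units) if units is not None else matrix
    word_mask = sub.events["domain"].notna().to_numpy()
    X = sub.rates[:, word_mask].T
    y = sub.events.loc[word_mask, "domain"].to_numpy(dtype=int)
    sentences = sub.events.loc[word_mask, "sentence_id"].to_numpy(dtype=int)
    return X, y, sentences, np.flatnonzero(word_mask)


def _run_iterations(
    X: np.ndarray,
    y: np.ndarray,
    sentences: np.ndarray,
    cfg: DecoderConfig,
    n_iterations: int,
    seed: int,
    track_events: bool = False,
) -> DecodingResult:
    domains = sorted(set(y))
    rng = rng_for(seed, "decode")
    uniq_sent = np.unique(sentences)
    n_train = max(1, int(round(cfg.train_fraction * len(uniq_sent))))
    accs, raws = [], []
    conf = np.zeros((len(domains), len(domains)), dtype=int)
    tested = np.zeros(len(y))
    correct = np.zeros(len(y))
    it = 0
    guard = 0
    while it < n_iterations:
        guard += 1
        if guard > 20 * n_iterations:
            raise RuntimeError("could not draw splits containing every domain")
        train_sent = rng.choice(uniq_sent, size=n_train, replace=False)
        train_mask = np.isin(sentences, train_sent)
        if len(set(y[train_mask])) < len(domains) or not np.any(~train_mask):
            warnings.warn("a domain was absent from the training split; resampled")
            continue
        clf = cfg.make_classifier()
        Xtr, Xte = X[train_mask], X[~train_mask]
        if cfg.standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf.fit(Xtr, y[train_mask])
        pred = clf.predict(Xte)
        accs.append(balanced_accuracy_score(y[~train_mask], pred))
        raws.append(float((pred == y[~train_mask]).mean()))
        conf += confusion_matrix(y[~train_mask], pred, labels=domains)
        if track_events:
            te_idx = np.flatnonzero(~train_mask)
            tested[te_idx] += 1
            correct[te_idx] += (pred == y[~train_mask]).astype(float)
        it += 1
    return DecodingResult(
        np.asarray(accs), np.asarray(raws), confusion=conf, domains=domains,
        per_event_tested=tested if track_events else None,
        per_event_correct=correct if track_events else None,
    )


def decode_domains(
    matrix: ResponseMatrix,
    partition: DomainPartition | None,
    units=None,
    cfg: DecoderConfig | None = None,
    n_iterations: int | None = None,
    track_events: bool = False,
) -> DecodingResult:
    """Decode per-word semantic domains over repeated sentence-level splits.

    `partition` is carried for interface symmetry; labels are taken from the
    event metadata (ground-truth or clustering-assigned domains). `units`
    defaults to all units in the matrix — pass the selective set for the
    headline analysis.
    """
    cfg = cfg or DecoderConfig()
    X, y, sentences, _ = _features_labels(matrix, units)
    if len(set(y)) < 2:
        raise ValueError("need at least two domains to decode")
    return _run_iterations(
        X, y, sentences, cfg,
        n_iterations or cfg.n_iterations, cfg.seed, track_events,
    )


def permutation_null(
    matrix: ResponseMatrix,
    partition: DomainPartition | None,
    units=None,
    cfg: DecoderConfig | None = None,
    observed: float | None = None,
    n_permutations: int | None = None,
    plus_one: bool = False,
) -> tuple[np.ndarray, float]:
    """Label-shuffled null distribution of decoding accuracy.

    Each permutation shuffles the domain labels over events, then runs one
    sentence-level train/test split through the identical pipeline. The
    empirical p is the fraction of permutations with accuracy >= the observed
    mean (optionally with +1 smoothing so p is never exactly 0).
    """
    cfg = cfg or DecoderConfig()
    n_perm = n_permutations or cfg.n_permutations
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-value resolution is coarse")
    X, y, sentences, _ = _features_labels(matrix, units)
    if observed is None:
        observed = decode_domains(matrix, partition, units, cfg).mean_accuracy
    rng = rng_for(cfg.seed, "permutation")
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        res = _run_iterations(
            X, y_perm, sentences, cfg, 1, child_seed(cfg.seed, "perm", i)
        )
        null[i] = res.mean_accuracy
    if plus_one:
        p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    else:
        p = float((null >= observed).mean())
        p = max(p, 1.0 / n_perm)  # empirical p cannot be claimed smaller
    return null, p


def generalize_across_materials(
    matrix_train: ResponseMatrix,
    matrix_test: ResponseMatrix,
    partition: DomainPartition | None,
    units=None,
    cfg: DecoderConfig | None = None,
    n_permutations: int | None = None,
) -> DecodingResult:
    """Train on all sentence events, evaluate on story events.

    The story vocabulary may be partially novel; labels must come from the
    same domain set. Accuracy is compared against a label-shuffled null on
    the story side.
    """
    cfg = cfg or DecoderConfig()
    if len(matrix_test.events) == 0:
        raise ValueError("story (test) matrix has no events")
    Xtr, ytr, _, _ = _features_labels(matrix_train, units)
    Xte, yte, _, _ = _features_labels(matrix_test, units)
    shared = sorted(set(ytr) & set(yte))
    keep = np.isin(yte, shared)
    Xte, yte = Xte[keep], yte[keep]
    if cfg.standardize:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    clf = cfg.make_classifier()
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    acc = balanced_accuracy_score(yte, pred)
    raw = float((pred == yte).mean())
    rng = rng_for(cfg.seed, "story_null")
    n_perm = n_permutations or cfg.n_permutations
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = balanced_accuracy_score(rng.permutation(yte), pred)
    p = max(float((null >= acc).mean()), 1.0 / n_perm)
    return DecodingResult(
        np.array([acc]), np.array([raw]), null=null, p_value=p,
        confusion=confusion_matrix(yte, pred, labels=sorted(set(ytr))),
        domains=sorted(set(ytr)),
    )


def improvement_surface(
    matrix: ResponseMatrix,
    table: EmbeddingTable,
    d_range=range(2, 21),
    n_units_range=None,
    cfg: DecoderConfig | None = None,
    n_iterations: int = 200,
) -> pd.DataFrame:
    """Decoding improvement over shuffle as domain count and unit count vary.

    At each d the vocabulary is re-clustered by spherical k-means; at each n
    a random unit subset is drawn. improvement(d, n) =
    100 * (PA_actual - PA_shuffle) / PA_actual, undefined (NaN, flagged) when
    PA_actual is 0.
    """
    cfg = cfg or DecoderConfig()
    if n_units_range is None:
        n_units_range = [matrix.n_units]
    rows = []
    word_mask = matrix.events["domain"].notna().to_numpy()
    tokens = matrix.events["token"].to_numpy()
    for d in d_range:
        part_d = spherical_kmeans(table, int(d), seed=child_seed(cfg.seed, "surface", d))
        labels_d = np.array(
            [part_d.domain_of(t) if word_mask[i] else -1
             for i, t in enumerate(tokens)]
        )
        for n in n_units_range:
            rng = rng_for(cfg.seed, "surface_units", d, n)
            units = list(rng.choice(matrix.unit_ids, size=int(n), replace=False))
            sub = matrix.subset_units(units)
            X = sub.rates[:, word_mask].T
            y = labels_d[word_mask]
            sentences = sub.events.loc[word_mask, "sentence_id"].to_numpy(dtype=int)
            if len(set(y)) < 2:
                continue
            actual = _run_iterations(
                X, y, sentences, cfg, n_iterations, child_seed(cfg.seed, "act", d, n)
            ).mean_accuracy
            rng2 = rng_for(cfg.seed, "surface_shuffle", d, n)
            shuffled = _run_iterations(
                X, rng2.permutation(y), sentences, cfg, n_iterations,
                child_seed(cfg.seed, "shuf", d, n)
            ).mean_accuracy
            if actual == 0:
                warnings.warn(f"PA_actual=0 at (d={d}, n={n}); improvement undefined")
                imp = float("nan")
            else:
                imp = 100.0 * (actual - shuffled) / actual
            rows.append({"d": int(d), "n_units": int(n), "pa_actual": actual,
                         "pa_shuffle": shuffled, "improvement": imp})
    return pd.DataFrame(rows)
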