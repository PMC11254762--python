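"""Per-neuron semantic selectivity statistics.

A unit is semantically selective when its firing rate for words of some
domain differs from its rate for all other words (two-sided rank-sum test per
domain, Benjamini-Hochberg FDR-adjusted across the k domains per unit). The
magnitude of tuning is the selectivity index

    SI = |FR_domain - FR_other| / (FR_domain + FR_other),

0 for no tuning and 1 for an exclusively tuned unit. Robustness is probed by
sentence-level 60/40 bootstrap splits, a meaning-specificity curve that
restricts each domain to its centroid-nearest words, and a word/nonword
contrast (Welch t-test per unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import rng_for
from .alignment import ResponseMatrix
from .embeddings import DomainPartition, EmbeddingTable

__all__ = [
    "SelectivityResult",
    "domain_selectivity",
    "selectivity_index",
    "bootstrap_si",
    "specificity_curve",
    "word_nonword_test",
]


@dataclass
class UnitSelectivity:
    unit_id: int
    p_raw: dict[int, float]
    p_adj: dict[int, float]
    significant_domains: list[int]
    preferred_domain: int | None
    si: float  # NaN when undefined (both mean rates zero)
    fr_domain: float
    fr_other: float

    @property
    def selective(self) -> bool:
        return bool(self.significant_domains)


@dataclass
class SelectivityResult:
    units: dict[int, UnitSelectivity]
    alpha: float

    def selective_units(self) -> list[int]:
        return [u for u, r in self.units.items() if r.selective]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, r in self.units.items():
            for d in sorted(r.p_raw):
                rows.append(
                    {"unit": u, "domain": d, "p_raw": r.p_raw[d],
                     "p_adj": r.p_adj[d], "significant": d in r.significant_domains,
                     "preferred": d == r.preferred_domain, "si": r.si,
                     "fr_domain": r.fr_domain, "fr_other": r.fr_other}
                )
        return pd.DataFrame(rows)


def _domain_masks(matrix: ResponseMatrix, partition: DomainPartition):
    domains = matrix.events["domain"].to_numpy()
    return {d: domains == d for d in range(1, partition.k + 1)}


def selectivity_index(
    matrix: ResponseMatrix, partition: DomainPartition, unit: int, domain: int
) -> float:
    """SI = |FR_domain - FR_other| / (FR_domain + FR_other) for one unit.

    Undefined (NaN) when both mean rates are zero, mirroring the exclusion of
    zero-firing-rate units from group statistics.
    """
    if not 1 <= domain <= partition.k:
        raise ValueError(f"unknown domain {domain}")
    rates = matrix.unit_row(unit)
    mask = matrix.events["domain"].to_numpy() == domain
    if not mask.any() or mask.all():
        raise ValueError("domain has no events (or no complement) in matrix")
    fr_d = rates[mask].mean()
    fr_o = rates[~mask].mean()
    return _si_from_means(fr_d, fr_o)


def _si_from_means(fr_d: float, fr_o: float) -> float:
    denom = abs(fr_d + fr_o)
    if denom == 0:
        return float("nan")
    return abs(fr_d - fr_o) / denom


def domain_selectivity(
    matrix: ResponseMatrix,
    partition: DomainPartition,
    alpha: float = 0.05,
    min_events: int = 2,
) -> SelectivityResult:
    """Rank-sum test per unit per domain, BH-adjusted across the k domains.

    A unit is selective iff any adjusted p < alpha. The preferred domain is
    the significant domain with the smallest adjusted p (ties broken by the
    larger |FR_domain - FR_other|, then the lower domain index).
    """
    masks = _domain_masks(matrix, partition)
    word_mask = matrix.events["domain"].notna().to_numpy()
    units: dict[int, UnitSelectivity] = {}
    for r, u in enumerate(matrix.unit_ids):
        rates = matrix.rates[r]
        p_raw: dict[int, float] = {}
        effects: dict[int, tuple[float, float, float]] = {}
        for d, mask in masks.items():
            n_in = int(mask.sum())
            if n_in < min_events or (word_mask & ~mask).sum() < min_events:
                warnings.warn(f"domain {d}: <{min_events} events; skipped")
                continue
            x = rates[mask]
            y = rates[word_mask & ~mask]
            p_raw[d] = float(stats.ranksums(x, y).pvalue)
            effects[d] = (x.mean(), y.mean(), abs(x.mean() - y.mean()))
        doms = sorted(p_raw)
        if doms:
            _, p_adj_arr, _, _ = multipletests(
                [p_raw[d] for d in doms], alpha=alpha, method="fdr_bh"
            )
            p_adj = {d: float(p) for d, p in zip(doms, p_adj_arr)}
        else:
            p_adj = {}
        sig = [d for d in doms if p_adj[d] < alpha]
        preferred = None
        if sig:
            preferred = min(sig, key=lambda d: (p_adj[d], -effects[d][2], d))
        elif doms:
            # non-selective units still get a nominal best domain for SI
            preferred = min(doms, key=lambda d: (p_adj[d], -effects[d][2], d))
        if preferred is not None:
            fr_d, fr_o, _ = effects[preferred]
            si = _si_from_means(fr_d, fr_o)
        else:
            fr_d = fr_o = si = float("nan")
        units[u] = UnitSelectivity(u, p_raw, p_adj, sig, preferred if sig else
                                   (preferred if preferred is not None else None),
                                   si, fr_d, fr_o)
    return SelectivityResult(units, alpha)


def bootstrap_si(
    matrix: ResponseMatrix,
    partition: DomainPartition,
    unit: int,
    n_iter: int = 100,
    split: float = 0.6,
    seed: int = 0,
    alpha: float = 0.05,
    preferred: int | None = None,
) -> tuple[np.ndarray, float]:
    """Sentence-level 60% subsample robustness of a unit's SI.

    Returns the SI distribution over iterations and the cross-domain rate:
    the fraction of iterations in which some *non-preferred* domain reaches
    BH-adjusted significance for this unit.
    """
    if preferred is None:
        res = domain_selectivity(matrix, partition, alpha)
        preferred = res.units[unit].preferred_domain
    sent_ids = matrix.events.loc[
        matrix.events["domain"].notna(), "sentence_id"
    ].unique()
    rng = rng_for(seed, "bootstrap_si", unit)
    sis, cross = [], 0
    done = resampled = 0
    while done < n_iter:
        take = rng.choice(sent_ids, size=max(1, int(round(split * len(sent_ids)))),
                          replace=False)
        mask = matrix.events["sentence_id"].isin(take).to_numpy()
        sub_domains = matrix.events.loc[mask, "domain"]
        present = set(sub_domains.dropna().astype(int))
        if len(present) < partition.k:
            resampled += 1
            continue
        sub = matrix.subset_units([unit])
        from dataclasses import replace as _replace
        sub = _replace(sub, rates=sub.rates[:, mask],
                       events=matrix.events.loc[mask].reset_index(drop=True))
        sis.append(selectivity_index(sub, partition, unit, preferred))
        res = domain_selectivity(sub, partition, alpha)
        sig = set(res.units[unit].significant_domains)
        if sig - {preferred}:
            cross += 1
        done += 1
    if resampled > 0.1 * n_iter:
        warnings.warn(f"{resampled} subsamples lost a domain and were redrawn")
    return np.asarray(sis), cross / n_iter


def nearest_to_centroid(
    partition: DomainPartition,
    table: EmbeddingTable,
    fraction: float,
) -> set[str]:
    """The ceil(fraction * n_d) words of each domain closest (cosine) to its
    centroid — the increasingly specific vocabularies of the specificity
    curve."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    kept: set[str] = set()
    for d in range(1, partition.k + 1):
        members = partition.members(d)
        dists = {}
        for w in members:
            v = table.vector(w)
            dists[w] = 1.0 - float(
                v / np.linalg.norm(v) @ partition.centroids[d - 1])
        ordered = sorted(members, key=lambda w: (dists[w], w))
        kept.update(ordered[: int(np.ceil(fraction * len(members)))])
    return kept


def specificity_curve(
    matrix: ResponseMatrix,
    partition: DomainPartition,
    table: EmbeddingTable,
    fractions: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25),
    units: list[int] | None = None,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean SI of selective units as each domain narrows to its centroid-nearest
    words (increasing meaning specificity).

    At fraction f, only the ceil(f * n_d) words of each domain closest (cosine)
    to the domain centroid are kept, and SIs are recomputed over the same
    units. Returns a table of fraction / mean_si / ci_low / ci_high / n_units.
    """
    if units is None:
        units = domain_selectivity(matrix, partition, alpha).selective_units()
    base = domain_selectivity(matrix, partition, alpha)
    pref = {u: base.units[u].preferred_domain for u in units}

    rng = rng_for(seed, "specificity")
    rows = []
    for f in fractions:
        kept = nearest_to_centroid(partition, table, f)
        if any(
            sum(1 for w in kept if partition.domain_of(w) == d) < 2
            for d in range(1, partition.k + 1)
        ):
            warnings.warn(f"fraction {f}: a domain was left <2 words; skipped")
            continue
        mask = matrix.events["token"].isin(kept).to_numpy()
        from dataclasses import replace as _replace
        sub = _replace(matrix, rates=matrix.rates[:, mask],
                       events=matrix.events.loc[mask].reset_index(drop=True))
        sis = []
        for u in units:
            d = pref[u]
            if d is None:
                continue
            dmask = sub.events["domain"].to_numpy() == d
            if not dmask.any() or dmask.all():
                continue
            sis.append(selectivity_index(sub, partition, u, d))
        sis = np.array([s for s in sis if np.isfinite(s)])
        if len(sis) == 0:
            continue
        boots = np.array([
            rng.choice(sis, size=len(sis), replace=True).mean() for _ in range(n_boot)
        ])
        rows.append({"fraction": f, "mean_si": sis.mean(),
                     "ci_low": np.percentile(boots, 2.5),
                     "ci_high": np.percentile(boots, 97.5), "n_units": len(sis)})
    return pd.DataFrame(rows)


def word_nonword_test(
    matrix: ResponseMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Welch two-tailed t-test per unit: word vs nonword firing rates.

    Returns unit / t / p / discriminating (p < alpha).
    """
    cond = matrix.events["condition"].to_numpy()
    word_mask = cond != "nonword"
    nw_mask = cond == "nonword"
    if not nw_mask.any():
        raise ValueError(
            "no nonword events; enable nonword_blocks in the generator"
        )
    rows = []
    for r, u in enumerate(matrix.unit_ids):
        t, p = stats.ttest_ind(matrix.rates[r, word_mask], matrix.rates[r, nw_mask],
                               equal_var=False)
        rows.append({"unit": u, "t": float(t), "p": float(p),
                     "discriminating": bool(p < alpha)})
    return pd.DataFrame(rows)
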