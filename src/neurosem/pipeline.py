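"""End-to-end orchestration: simulate -> cluster -> align -> selectivity ->
decode -> context -> space, with stage toggles and a deterministic report.

The pipeline is the library's batch entry point: one config, one seed, one
JSON-serialisable report containing every statistic it computed. Re-running
the same config and seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignment import align_responses, select_events
from .context import (
    BackoffBigramModel,
    homophone_contrast,
    sentence_vs_wordlist_si,
    surprisal,
    surprisal_decile_decoding,
)
from .decoding import DecoderConfig, decode_domains, generalize_across_materials, permutation_null
from .embeddings import purity, select_cluster_count, spherical_kmeans
from .selectivity import domain_selectivity, word_nonword_test
from .semantic_space import (
    cophenetic_hierarchy,
    distance_correlation,
    fit_embedding_regression,
    pca_space,
    rate_distance_correlation,
)
from .synthetic import GeneratorConfig, generate_session

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "cluster", "align", "selectivity", "decode", "context", "space")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full synthetic-session run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    window: tuple[float, float] = (0.1, 0.5)
    alpha: float = 0.05
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    n_decode_iterations: int = 200
    n_permutations: int = 200
    cluster_k_range: tuple[int, int] = (5, 20)
    cluster_repeats: int = 10
    n_pc: int = 5
    ridge_lambda: float = 1e-4
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages on one synthetic session and return the report.

    Stage failures raise with the stage name; the partial report assembled so
    far is attached to the exception as `partial_report`.
    """
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _to_jsonable(dataclasses.asdict(config)),
        "stages": {},
    }
    gen = dataclasses.replace(config.generator, seed=config.seed)
    session = matrix = partition_hat = None
    try:
        for stage in STAGES:
            if stage not in config.stages:
                report["stages"][stage] = "skipped"
                continue
            if stage == "simulate":
                session = generate_session(gen)
                report["stages"]["simulate"] = {
                    "n_units": gen.n_units,
                    "n_events": len(session.events),
                    "n_words": len(session.table),
                    "n_selective_planted": len(session.spikes.selective_units()),
                }
            elif stage == "cluster":
                k_star, crit = select_cluster_count(
                    session.table, config.cluster_k_range,
                    n_repeats=config.cluster_repeats, seed=config.seed,
                )
                partition_hat = spherical_kmeans(session.table, k_star,
                                                 seed=config.seed)
                pur = None
                if k_star == session.partition.k:
                    pur = purity(partition_hat, session.partition)
                report["stages"]["cluster"] = {
                    "k_star": k_star, "k_mode": crit.attrs["k_mode"],
                    "purity_vs_planted": pur,
                    "criterion": _to_jsonable(crit.to_dict(orient="list")),
                }
            elif stage == "align":
                matrix = align_responses(session.spikes, session.events,
                                         config.window)
                report["stages"]["align"] = {
                    "window": list(config.window),
                    "n_events": matrix.n_events,
                    "mean_rate": float(matrix.rates.mean()),
                }
            elif stage == "selectivity":
                sent = select_events(matrix, conditions="sentence")
                sel = domain_selectivity(sent, session.partition, config.alpha)
                sel_units = sel.selective_units()
                sis = [sel.units[u].si for u in sel_units
                       if np.isfinite(sel.units[u].si)]
                try:
                    nw = word_nonword_test(matrix, config.alpha)
                    nw_frac = float(nw["discriminating"].mean())
                except ValueError:
                    nw_frac = None
                report["stages"]["selectivity"] = {
                    "n_selective": len(sel_units),
                    "frac_selective": len(sel_units) / matrix.n_units,
                    "mean_si": float(np.mean(sis)) if sis else None,
                    "frac_word_nonword": nw_frac,
                }
                report["_selective_units"] = sel_units
            elif stage == "decode":
                sent = select_events(matrix, conditions="sentence")
                units = report.get("_selective_units") or matrix.unit_ids
                res = decode_domains(sent, session.partition, units,
                                     config.decoder,
                                     n_iterations=config.n_decode_iterations)
                null, p = permutation_null(
                    sent, session.partition, units, config.decoder,
                    observed=res.mean_accuracy,
                    n_permutations=config.n_permutations,
                )
                report["stages"]["decode"] = {
                    **res.summary(), "null_mean": float(null.mean()), "p": p,
                    "chance": 1.0 / session.partition.k,
                }
            elif stage == "context":
                units = report.get("_selective_units") or matrix.unit_ids
                ctx: dict = {}
                try:
                    wl = sentence_vs_wordlist_si(matrix, session.partition,
                                                 alpha=config.alpha)
                    ctx["sentence_vs_wordlist"] = {
                        k: v for k, v in wl.items() if k != "units"}
                except ValueError as e:
                    ctx["sentence_vs_wordlist"] = f"unavailable: {e}"
                try:
                    hc = homophone_contrast(matrix, matrix.events,
                                            session.partition, units=units,
                                            n_perm=2000, seed=config.seed)
                    ctx["homophone"] = {k: v for k, v in hc.items()
                                        if k != "scatter"}
                except ValueError as e:
                    ctx["homophone"] = f"unavailable: {e}"
                sent_events = [e for e in session.events
                               if e.condition == "sentence"]
                lm = BackoffBigramModel(_sentences_of(sent_events))
                s = surprisal(matrix.events, lm)
                ctx["surprisal_deciles"] = surprisal_decile_decoding(
                    matrix, session.partition, units, s, config.decoder,
                    n_iterations=min(100, config.n_decode_iterations),
                )
                report["stages"]["context"] = _to_jsonable(ctx)
            elif stage == "space":
                theta, words = fit_embedding_regression(
                    matrix.zscore(), session.table, config.ridge_lambda)
                space = pca_space(theta, session.table, config.n_pc,
                                  config.ridge_lambda, words)
                # pair-distance and hierarchy analyses run on the selective
                # subpopulation, where semantic geometry is carried
                sel_units = report.get("_selective_units") or matrix.unit_ids
                msel = matrix.subset_units(sel_units)
                rdc = rate_distance_correlation(msel, session.table,
                                                n_perm=200, seed=config.seed)
                coph = cophenetic_hierarchy(session.table, msel)
                report["stages"]["space"] = {
                    "explained_variance": _to_jsonable(space.explained_variance),
                    "rate_distance_r": rdc["r"], "rate_distance_p": rdc["p"],
                    "cophenetic_r": coph["r"],
                }
    except Exception as e:
        e.partial_report = report  # type: ignore[attr-defined]
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    report.pop("_selective_units", None)
    report = _to_jsonable(report)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    return report


def _sentences_of(events) -> list[list[str]]:
    by_sid: dict[int, list[tuple[int, str]]] = {}
    for ev in events:
        by_sid.setdefault(ev.sentence_id, []).append((ev.position, ev.token))
    return [[t for _, t in sorted(v)] for _, v in sorted(by_sid.items())]
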