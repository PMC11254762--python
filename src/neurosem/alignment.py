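"""Word-aligned firing rates: the response matrix analysed downstream.

Responses are counted in a fixed window per word (default 100-500 ms after
onset, i.e. a 400-ms window with a 100-ms lag for evoked-response delay) and
expressed as rates in spikes/s. Windows are half-open [start, end) so a spike
on a boundary is counted exactly once; at ~341-ms word spacing consecutive
windows overlap, which is why the every-other-word control exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic import SpikeData, WordEvent, events_to_frame

__all__ = ["ResponseMatrix", "align_responses", "select_events"]


@dataclass
class ResponseMatrix:
    """Units x events matrix of in-window firing rates plus event metadata."""

    rates: np.ndarray  # (n_units, n_events), spikes/s
    unit_ids: list[int]
    events: pd.DataFrame  # one row per column of `rates`
    window: tuple[float, float]  # (lag_s, end_s) relative to word onset
    zscored: bool = False

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        lag, end = self.window
        if not (end > lag >= 0):
            raise ValueError("window must satisfy end > lag >= 0")
        if self.rates.shape != (len(self.unit_ids), len(self.events)):
            raise ValueError("rates shape does not match units x events")
        if not self.zscored and np.any(self.rates < 0):
            raise ValueError("raw rates must be non-negative")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]

    def unit_row(self, unit_id: int) -> np.ndarray:
        return self.rates[self.unit_ids.index(unit_id)]

    def subset_units(self, unit_ids) -> "ResponseMatrix":
        unit_ids = list(unit_ids)
        idx = [self.unit_ids.index(u) for u in unit_ids]
        return replace(self, rates=self.rates[idx], unit_ids=unit_ids)

    def zscore(self) -> "ResponseMatrix":
        """Per-unit z-scoring across events (constant units map to 0)."""
        mu = self.rates.mean(axis=1, keepdims=True)
        sd = self.rates.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return replace(self, rates=(self.rates - mu) / sd, zscored=True)

    def word_means(self) -> pd.DataFrame:
        """Mean rate per unique token (units as rows, tokens as columns)."""
        tokens = self.events["token"].to_numpy()
        uniq = pd.unique(tokens)
        cols = {t: self.rates[:, tokens == t].mean(axis=1) for t in uniq}
        return pd.DataFrame(cols, index=self.unit_ids)

    def write_tsv(self, path, sidecar=None) -> None:
        df = pd.DataFrame(self.rates.T, columns=[str(u) for u in self.unit_ids])
        pd.concat([self.events.reset_index(drop=True), df], axis=1).to_csv(
            path, sep="\t", index=False
        )
        if sidecar is not None:
            meta = {"window": list(self.window), "zscored": self.zscored,
                    "convention": "half-open [onset+lag, onset+end), rates in sp/s"}
            with open(sidecar, "w") as fh:
                json.dump(meta, fh, indent=1)


def align_responses(
    spikes: SpikeData,
    events: list[WordEvent] | pd.DataFrame,
    window: tuple[float, float] = (0.1, 0.5),
    zscore: bool = False,
) -> ResponseMatrix:
    """Count spikes in [onset+lag, onset+end) per unit per word and divide by
    the window duration.

    The +-50 ms robustness variants use windows (0.1, 0.45) and (0.1, 0.55).
    """
    lag, end = window
    if lag < 0 or end <= lag:
        raise ValueError("window must satisfy end > lag >= 0")
    ev_df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    onsets = ev_df["onset"].to_numpy(dtype=float)
    starts, stops = onsets + lag, onsets + end
    unit_ids = sorted(spikes.spikes)
    rates = np.empty((len(unit_ids), len(ev_df)))
    dur = end - lag
    for r, u in enumerate(unit_ids):
        st = np.asarray(spikes.spikes[u])
        # half-open interval: searchsorted 'left' at start, 'left' at stop
        rates[r] = (np.searchsorted(st, stops, side="left")
                    - np.searchsorted(st, starts, side="left")) / dur
    out = ResponseMatrix(rates, unit_ids, ev_df.reset_index(drop=True), window)
    return out.zscore() if zscore else out


def select_events(
    matrix: ResponseMatrix,
    conditions: str | list[str] | None = None,
    position_parity: str | None = None,
    domains: list[int] | None = None,
    sentence_ids: list[int] | None = None,
    predicate=None,
) -> ResponseMatrix:
    """Column-subset of the response matrix by event metadata.

    Filters compose as an intersection. `position_parity` of "odd"/"even"
    implements the every-other-word (non-neighbouring) control; `predicate`
    is an arbitrary row -> bool callable for anything else.
    """
    ev = matrix.events
    mask = np.ones(len(ev), dtype=bool)
    if conditions is not None:
        if isinstance(conditions, str):
            conditions = [conditions]
        mask &= ev["condition"].isin(conditions).to_numpy()
    if position_parity is not None:
        if position_parity not in ("odd", "even"):
            raise ValueError("position_parity must be 'odd' or 'even'")
        rem = 1 if position_parity == "odd" else 0
        mask &= (ev["position"].to_numpy() % 2 == rem)
    if domains is not None:
        mask &= ev["domain"].isin(domains).to_numpy()
    if sentence_ids is not None:
        mask &= ev["sentence_id"].isin(sentence_ids).to_numpy()
    if predicate is not None:
        mask &= ev.apply(predicate, axis=1).to_numpy(dtype=bool)
    if not mask.any():
        raise ValueError("event selection is empty")
    return replace(
        matrix,
        rates=matrix.rates[:, mask],
        events=ev.loc[mask].reset_index(drop=True),
    )
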