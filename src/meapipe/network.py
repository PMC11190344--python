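"""Array-wide network bursts and STTC functional connectivity.

A *network burst* (NB) is a cluster in the pooled spike train of one well:
a maximal run of pooled spikes whose consecutive inter-spike intervals are
all <= 100 ms, containing at least 50 spikes from at least 5 distinct
electrodes. NB duration is first-to-last member spike.

The *spike time tiling coefficient* (STTC) between spike trains A and B is

    STTC = 1/2 * ( (P_A - T_B)/(1 - P_A*T_B) + (P_B - T_A)/(1 - P_B*T_A) )

where P_A is the fraction of A's spikes lying within +-dt of any B spike,
and T_A is the fraction of the recording covered by the union of +-dt
windows around A's spikes (windows clipped to [0, duration], overlaps
merged — exact interval arithmetic, not rasterization). STTC is symmetric,
lies in [-1, 1], is ~0 for independent trains regardless of rate, and is 1
for identical non-degenerate trains. A term with numerator and denominator
both 0 is defined as 0; an empty train makes the coefficient undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .spikeio import Recording
from .stats import sample_skewness

__all__ = [
    "NetworkBurst",
    "NBStats",
    "STTCSummary",
    "detect_network_bursts",
    "nb_stats",
    "sttc_pair",
    "sttc_summary",
    "network_bursts_to_frame",
]

DEFAULT_NB_MAX_ISI_S = 0.100
DEFAULT_NB_MIN_SPIKES = 50
DEFAULT_NB_MIN_CHANNELS = 5
DEFAULT_STTC_DT_S = 0.100


@dataclass(frozen=True)
class NetworkBurst:
    times_s: tuple[float, ...]  # pooled member spike times, sorted
    electrodes: tuple[str, ...]  # electrode of each member spike

    @property
    def start_s(self) -> float:
        return self.times_s[0]

    @property
    def end_s(self) -> float:
        return self.times_s[-1]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_spikes(self) -> int:
        return len(self.times_s)

    @property
    def channels(self) -> frozenset[str]:
        return frozenset(self.electrodes)


def detect_network_bursts(
    recording: Recording,
    well_id: str,
    max_isi_s: float = DEFAULT_NB_MAX_ISI_S,
    min_spikes: int = DEFAULT_NB_MIN_SPIKES,
    min_channels: int = DEFAULT_NB_MIN_CHANNELS,
) -> list[NetworkBurst]:
    """Detect NBs in the pooled spike train of one well.

    The pool is sorted by time with ties broken by electrode label (stable);
    maximal clusters are cut at pooled gaps > ``max_isi_s`` (inclusive
    boundary stays within a cluster) and kept when they meet both minima.
    """
    sub = recording.spikes.well(well_id)
    if sub.empty:
        return []
    times = sub["time_s"].to_numpy(float)
    elecs = sub["electrode"].to_numpy(str)
    return detect_network_bursts_pooled(times, elecs, max_isi_s, min_spikes, min_channels)


def detect_network_bursts_pooled(
    times: np.ndarray,
    elecs: np.ndarray,
    max_isi_s: float = DEFAULT_NB_MAX_ISI_S,
    min_spikes: int = DEFAULT_NB_MIN_SPIKES,
    min_channels: int = DEFAULT_NB_MIN_CHANNELS,
) -> list[NetworkBurst]:
    """NB detection on pre-pooled (time, electrode) arrays."""
    order = np.lexsort((elecs, times))
    times, elecs = times[order], elecs[order]
    # inclusive threshold with 1e-9 relative slack (float-representation guard)
    breaks = np.flatnonzero(np.diff(times) > max_isi_s * (1.0 + 1e-9)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [times.size]))
    out: list[NetworkBurst] = []
    for s, e in zip(starts, ends):
        if e - s >= min_spikes and len(set(elecs[s:e])) >= min_channels:
            out.append(NetworkBurst(tuple(times[s:e]), tuple(elecs[s:e])))
    return out


@dataclass(frozen=True)
class NBStats:
    """Well-level NB summary consumed by the parameter vectors."""

    n_nbs: int
    nb_rate_hz: float
    mean_nb_duration_s: float
    mean_spikes_per_nb: float
    mean_channels_per_nb: float
    pct_spikes_in_nbs: float
    mean_inter_nb_interval_s: float  # onset-to-onset; NaN with < 2 NBs


def nb_stats(nbs: Sequence[NetworkBurst], recording: Recording, well_id: str) -> NBStats:
    return nb_stats_from_counts(
        nbs, recording.duration_s, len(recording.spikes.well(well_id))
    )


def nb_stats_from_counts(
    nbs: Sequence[NetworkBurst], duration_s: float, n_total: int
) -> NBStats:
    n = len(nbs)
    if n == 0:
        return NBStats(0, 0.0, math.nan, math.nan, math.nan,
                       0.0 if n_total else math.nan, math.nan)
    onsets = np.array([nb.start_s for nb in nbs])
    in_nb = sum(nb.n_spikes for nb in nbs)
    return NBStats(
        n_nbs=n,
        nb_rate_hz=n / duration_s,
        mean_nb_duration_s=float(np.mean([nb.duration_s for nb in nbs])),
        mean_spikes_per_nb=float(np.mean([nb.n_spikes for nb in nbs])),
        mean_channels_per_nb=float(np.mean([len(nb.channels) for nb in nbs])),
        pct_spikes_in_nbs=100.0 * in_nb / n_total if n_total else math.nan,
        mean_inter_nb_interval_s=float(np.mean(np.diff(onsets))) if n >= 2 else math.nan,
    )


def network_bursts_to_frame(nbs: Sequence[NetworkBurst]) -> pd.DataFrame:
    """NB list as a table (start, end, duration, n_spikes, n_channels) for CSV export."""
    return pd.DataFrame(
        [
            {"start_s": nb.start_s, "end_s": nb.end_s, "duration_s": nb.duration_s,
             "n_spikes": nb.n_spikes, "n_channels": len(nb.channels)}
            for nb in nbs
        ],
        columns=["start_s", "end_s", "duration_s", "n_spikes", "n_channels"],
    )


def _tiled_fraction(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """P_A: fraction of spikes in `a` within +-dt (inclusive) of any spike in `b`.

    Implemented as one searchsorted against windows shifted by dt: spike a_i
    is tiled iff the nearest b is within dt, i.e. iff searchsorted(b, a-dt)
    points at a b spike <= a+dt.
    """
    idx = b.searchsorted(a - dt, side="left")
    ok = idx < b.size
    hits = np.count_nonzero(b[idx[ok]] <= a[ok] + dt)
    return hits / a.size

def _covered_fraction(a: np.ndarray, dt: float, duration: float) -> float:
    """T_A: fraction of [0, duration] covered by the union of clipped +-dt windows.

    Full coverage is snapped to exactly 1.0 (relative slack 1e-12) so the
    degenerate 0/0 term rule fires consistently; float summation could
    otherwise land an epsilon above or below 1.
    """
    starts = np.clip(a - dt, 0.0, duration)
    ends = np.clip(a + dt, 0.0, duration)
    prev_end = np.concatenate(([-np.inf], ends[:-1]))  # ends nondecreasing for sorted a
    covered = float(np.clip(ends - np.maximum(starts, prev_end), 0.0, None).sum())
    if duration - covered <= duration * 1e-12:
        return 1.0
    return covered / duration


def _term(p: float, t: float) -> float:
    num = p - t
    den = 1.0 - p * t
    if den == 0.0:
        return 0.0  # only reachable with num == 0 (p = t = 1)
    return num / den


def sttc_pair(
    train_a: Sequence[float] | np.ndarray,
    train_b: Sequence[float] | np.ndarray,
    duration_s: float,
    dt_s: float = DEFAULT_STTC_DT_S,
) -> float:
    """STTC of two sorted spike trains on [0, duration_s]; NaN if either is empty."""
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    a = np.asarray(train_a, float)
    b = np.asarray(train_b, float)
    if a.size == 0 or b.size == 0:
        return math.nan
    p_a = _tiled_fraction(a, b, dt_s)
    p_b = _tiled_fraction(b, a, dt_s)
    t_a = _covered_fraction(a, dt_s, duration_s)
    t_b = _covered_fraction(b, dt_s, duration_s)
    return 0.5 * (_term(p_a, t_b) + _term(p_b, t_a))


@dataclass
class STTCSummary:
    matrix: pd.DataFrame  # symmetric electrode x electrode; NaN = undefined
    mean_sttc: float
    skewness_sttc: float
    n_pairs_used: int
    zero_variance: bool = False
    restricted_to_nb: bool = False


def _restrict_trains_to_nbs(
    trains: dict[str, np.ndarray], nbs: Sequence[NetworkBurst]
) -> tuple[dict[str, np.ndarray], float]:
    """Concatenate NB windows [start, end] into one compressed time axis."""
    if not nbs:
        return {e: np.empty(0) for e in trains}, 0.0
    windows = sorted((nb.start_s, nb.end_s) for nb in nbs)
    offsets = np.concatenate(([0.0], np.cumsum([e - s for s, e in windows])))
    total = float(offsets[-1])
    out = {}
    for elec, t in trains.items():
        pieces = []
        for (s, e), off in zip(windows, offsets[:-1]):
            sel = t[(t >= s) & (t <= e)]
            if sel.size:
                pieces.append(sel - s + off)
        out[elec] = np.concatenate(pieces) if pieces else np.empty(0)
    return out, total


def sttc_summary(
    recording: Recording,
    well_id: str,
    dt_s: float = DEFAULT_STTC_DT_S,
    restrict_to_nb: bool = False,
    nb_kwargs: dict | None = None,
) -> STTCSummary:
    """Pairwise STTC matrix of one well plus mean / sample skewness.

    Mean and skewness run over the defined upper-triangle entries only.
    With ``restrict_to_nb`` spike trains are first clipped to the union of
    NB windows (concatenated into a compressed time axis). All pair values
    identical (zero variance) yields skewness 0 with a flag so downstream
    parameter vectors stay complete.
    """
    trains = recording.spikes.trains(well_id)
    return sttc_summary_from_trains(
        trains, recording.duration_s, tuple(recording.layout.electrodes),
        dt_s=dt_s, restrict_to_nb=restrict_to_nb, nb_kwargs=nb_kwargs,
    )


def sttc_summary_from_trains(
    trains: dict[str, np.ndarray],
    duration_s: float,
    electrodes: tuple[str, ...],
    dt_s: float = DEFAULT_STTC_DT_S,
    restrict_to_nb: bool = False,
    nb_kwargs: dict | None = None,
) -> STTCSummary:
    """:func:`sttc_summary` on pre-extracted per-electrode trains."""
    duration = duration_s
    if restrict_to_nb:
        pooled_t = np.concatenate([t for t in trains.values()]) if trains else np.empty(0)
        pooled_e = np.concatenate(
            [np.repeat(e, t.size) for e, t in trains.items()]
        ) if trains else np.empty(0, dtype=str)
        nbs = detect_network_bursts_pooled(pooled_t, pooled_e, **(nb_kwargs or {}))
        trains, duration = _restrict_trains_to_nbs(trains, nbs)
    electrodes = list(electrodes)
    n = len(electrodes)
    mat = np.full((n, n), np.nan)
    nonempty = [i for i, e in enumerate(electrodes) if trains[e].size > 0]
    vals: list[float] = []
    if duration > 0:
        # the tiling term T depends on one train only: compute it once per electrode
        t_frac = {
            i: _covered_fraction(trains[electrodes[i]], dt_s, duration) for i in nonempty
        }
        for i in nonempty:
            mat[i, i] = 1.0
        for ii, i in enumerate(nonempty):
            a = trains[electrodes[i]]
            for j in nonempty[ii + 1:]:
                b = trains[electrodes[j]]
                v = 0.5 * (
                    _term(_tiled_fraction(a, b, dt_s), t_frac[j])
                    + _term(_tiled_fraction(b, a, dt_s), t_frac[i])
                )
                mat[i, j] = mat[j, i] = v
                vals.append(v)
    matrix = pd.DataFrame(mat, index=electrodes, columns=electrodes)
    if not vals:
        return STTCSummary(matrix, math.nan, math.nan, 0, restricted_to_nb=restrict_to_nb)
    arr = np.asarray(vals)
    zero_var = bool(np.all(arr == arr[0]))
    if zero_var or arr.size < 3:
        skew = 0.0 if zero_var else math.nan
    else:
        skew = sample_skewness(arr)
    return STTCSummary(
        matrix=matrix,
        mean_sttc=float(arr.mean()),
        skewness_sttc=skew,
        n_pairs_used=arr.size,
        zero_variance=zero_var,
        restricted_to_nb=restrict_to_nb,
    )
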