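"""Per-well spiking and single-electrode bursting metrics.

Definitions follow the standard multiwell-MEA conventions:

* MFR — total number of well spikes divided by recording time (Hz).
* wMFR — MFR weighted by the number of currently active electrodes
  ``e_act`` relative to the reference maximum ``e_max``; wtMFR uses the
  physical electrode count (16) as reference instead.
* An electrode is *active* (a contributing channel) when its spike rate is
  at least 0.1 Hz.
* A burst is a run of >= 5 consecutive spikes on one electrode with every
  inter-spike interval (ISI) <= 100 ms (inclusive); burst duration is
  first-to-last spike time.

The two printed weighting formulas use opposite ratios (wMFR scales up by
``e_max/e_act``, wMBR scales down by ``e_act/e_max``); both are exposed via
an explicit ``weighting`` flag and each metric defaults to its printed
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .spikeio import Recording

__all__ = [
    "SpikeMetrics",
    "Burst",
    "BurstMetrics",
    "active_electrodes",
    "weighted_rate",
    "spike_metrics",
    "detect_bursts",
    "burst_metrics",
]

DEFAULT_MIN_RATE_HZ = 0.1
DEFAULT_MAX_ISI_S = 0.100
DEFAULT_MIN_SPIKES = 5

Weighting = Literal["scale_up", "scale_down"]


@dataclass(frozen=True)
class SpikeMetrics:
    mfr_hz: float
    wmfr_hz: float
    wtmfr_hz: float
    mean_isi_s: float  # NaN when no active electrode has >= 2 spikes
    n_active: int
    e_max: int
    e_total: int
    degenerate: bool = False  # True when e_act = 0 and weighted rates fell back to 0


@dataclass(frozen=True)
class Burst:
    electrode_id: str
    spike_times_s: tuple[float, ...]

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)

    @property
    def duration_s(self) -> float:
        return self.spike_times_s[-1] - self.spike_times_s[0]


@dataclass(frozen=True)
class BurstMetrics:
    mbr_hz: float
    wmbr_hz: float
    mean_burst_duration_s: float  # NaN with zero bursts
    mean_spikes_per_burst: float  # NaN with zero bursts
    n_bursts: int


def weighted_rate(rate: float, e_act: int, e_max: int, weighting: Weighting) -> float:
    """Apply the active-electrode weighting; 0 (not inf) when e_act = 0."""
    if e_act == 0:
        return 0.0
    if e_max <= 0:
        raise ValueError("e_max must be >= 1")
    if weighting == "scale_up":
        return (e_max / e_act) * rate
    if weighting == "scale_down":
        return (e_act / e_max) * rate
    raise ValueError(f"unknown weighting {weighting!r}")


def _active_from_trains(
    trains: dict[str, np.ndarray], duration_s: float, min_rate_hz: float
) -> set[str]:
    # compare counts against the exact threshold (boundary inclusive)
    min_count = min_rate_hz * duration_s
    return {e for e, t in trains.items() if t.size >= min_count - 1e-9}


def active_electrodes(
    recording: Recording,
    well_id: str,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
) -> set[str]:
    """Electrodes whose spike rate is >= ``min_rate_hz`` (boundary inclusive)."""
    if recording.duration_s <= 0:
        raise ValueError("recording duration must be positive")
    return _active_from_trains(
        recording.spikes.trains(well_id), recording.duration_s, min_rate_hz
    )


def spike_metrics(
    recording: Recording,
    well_id: str,
    e_max: int | None = None,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
    e_total: int | None = None,
    weighting: Weighting = "scale_up",
) -> SpikeMetrics:
    """Well-level MFR / wMFR / wtMFR / mean ISI.

    ``e_max`` is the active-electrode count at the reference timepoint
    (defaults to the current count); ``e_total`` defaults to the physical
    layout size (16). Mean ISI pools within-electrode consecutive intervals
    over active electrodes; cross-electrode intervals are never formed.
    """
    if recording.duration_s <= 0:
        raise ValueError("recording duration must be positive")
    dur = recording.duration_s
    trains = recording.spikes.trains(well_id)
    return spike_metrics_from_trains(
        trains, dur, e_max=e_max, min_rate_hz=min_rate_hz,
        e_total=recording.layout.n_electrodes if e_total is None else e_total,
        weighting=weighting,
    )


def spike_metrics_from_trains(
    trains: dict[str, np.ndarray],
    duration_s: float,
    e_max: int | None = None,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
    e_total: int = 16,
    weighting: Weighting = "scale_up",
) -> SpikeMetrics:
    """:func:`spike_metrics` on pre-extracted per-electrode trains."""
    dur = duration_s
    active = _active_from_trains(trains, dur, min_rate_hz)
    e_act = len(active)
    if e_max is None:
        e_max = e_act
    mfr = sum(t.size for t in trains.values()) / dur
    degenerate = e_act == 0 and mfr > 0
    wmfr = weighted_rate(mfr, e_act, max(e_max, 1), weighting) if e_act else 0.0
    wtmfr = weighted_rate(mfr, e_act, e_total, weighting) if e_act else 0.0
    isis: list[np.ndarray] = []
    for elec in sorted(active):
        t = trains[elec]
        if t.size >= 2:
            isis.append(np.diff(t))
    mean_isi = float(np.concatenate(isis).mean()) if isis else math.nan
    return SpikeMetrics(
        mfr_hz=mfr,
        wmfr_hz=wmfr,
        wtmfr_hz=wtmfr,
        mean_isi_s=mean_isi,
        n_active=e_act,
        e_max=int(e_max),
        e_total=int(e_total),
        degenerate=degenerate,
    )


def detect_bursts(
    spike_times: Sequence[float] | np.ndarray,
    max_isi_s: float = DEFAULT_MAX_ISI_S,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    electrode_id: str = "",
) -> list[Burst]:
    """Maximal runs of consecutive spikes with every ISI <= ``max_isi_s``.

    Runs with at least ``min_spikes`` spikes are emitted as bursts; bursts
    are disjoint, ordered, and maximally extended (an adjacent spike within
    ``max_isi_s`` is always absorbed). The ISI boundary is inclusive.
    """
    t = np.asarray(spike_times, float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted ascending")
    if t.size < min_spikes:
        return []
    gaps = np.diff(t)
    # breakpoints where a new run starts; the threshold is inclusive with
    # 1e-9 relative slack so grid-spaced ISIs exactly at it stay in-burst
    breaks = np.flatnonzero(gaps > max_isi_s * (1.0 + 1e-9)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [t.size]))
    bursts: list[Burst] = []
    for s, e in zip(starts, ends):
        if e - s >= min_spikes:
            bursts.append(Burst(electrode_id, tuple(t[s:e])))
    return bursts


def detect_well_bursts(
    recording: Recording,
    well_id: str,
    max_isi_s: float = DEFAULT_MAX_ISI_S,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> list[Burst]:
    """Single-electrode bursts pooled over all electrodes of one well."""
    bursts: list[Burst] = []
    for elec, train in recording.spikes.trains(well_id).items():
        bursts.extend(detect_bursts(train, max_isi_s, min_spikes, electrode_id=elec))
    bursts.sort(key=lambda b: b.spike_times_s[0])
    return bursts


def burst_metrics(
    bursts: Iterable[Burst],
    recording: Recording,
    well_id: str,
    e_max: int | None = None,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
    weighting: Weighting = "scale_down",
) -> BurstMetrics:
    """Well-level burst rate metrics (MBR, wMBR, burst-shape means)."""
    bursts = list(bursts)
    dur = recording.duration_s
    e_act = len(active_electrodes(recording, well_id, min_rate_hz))
    return burst_metrics_from_counts(bursts, dur, e_act, e_max, weighting)


def burst_metrics_from_counts(
    bursts: list[Burst],
    duration_s: float,
    e_act: int,
    e_max: int | None = None,
    weighting: Weighting = "scale_down",
) -> BurstMetrics:
    """:func:`burst_metrics` on a pre-computed active-electrode count."""
    dur = duration_s
    if e_max is None:
        e_max = e_act
    mbr = len(bursts) / dur
    wmbr = weighted_rate(mbr, e_act, max(e_max, 1), weighting) if e_act else 0.0
    if bursts:
        mean_dur = float(np.mean([b.duration_s for b in bursts]))
        mean_n = float(np.mean([b.n_spikes for b in bursts]))
    else:
        mean_dur = math.nan
        mean_n = math.nan
    return BurstMetrics(
        mbr_hz=mbr,
        wmbr_hz=wmbr,
        mean_burst_duration_s=mean_dur,
        mean_spikes_per_burst=mean_n,
        n_bursts=len(bursts),
    )
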