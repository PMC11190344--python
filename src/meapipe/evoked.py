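"""Evoked-response quantification for test (STIM) and tetanic (TET)
stimulation protocols.

Per pulse, the evoked rate is the spike count in the 1 s half-open window
``[pulse, pulse + 1 s)`` divided by the window. Averaging over the pulses
of one session gives the electrode's evMFR'; dividing by the same
electrode's spontaneous rate from the preceding spontaneous block gives
evMFR_norm'; the grand mean over electrodes and sessions of a STIM block is
the well-level evMFR_norm (reported with its coefficient of variation and
sample skewness).

The tetanus effect per well is X = log10(evMFR_norm@STIM3) /
log10(evMFR_norm@STIM2); X = 1 means the tetanus changed nothing.
Experiments are aggregated per genotype as (mean of per-experiment means,
mean of per-experiment variances, total wells) and compared by Welch's t
test; the conventional S^2/n denominator is the default, the S^2/n^2
variant that some reports print is available by flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spikeio import Recording
from .stats import sample_skewness

__all__ = [
    "StimSession",
    "StimProtocol",
    "EvokedSummary",
    "TetComparison",
    "evoked_rate_per_pulse",
    "session_evoked_rate",
    "normalize_evoked",
    "well_evoked_summary",
    "analyze_stim_block",
    "tet_effect",
    "welch_aggregate_t",
]

DEFAULT_WINDOW_S = 1.0
DEFAULT_MIN_SPONT_RATE_HZ = 0.1


@dataclass(frozen=True)
class StimSession:
    session: int
    stim_electrode: str
    pulse_times_s: tuple[float, ...]  # within the STIM-block recording

    def __post_init__(self) -> None:
        t = np.asarray(self.pulse_times_s)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("pulse times must be strictly increasing")


@dataclass(frozen=True)
class StimProtocol:
    """One STIM block: ordered stimulation sessions (default 6 x 5 min at 0.2 Hz)."""

    block: str  # "STIM1" | "STIM2" | "STIM3"
    sessions: tuple[StimSession, ...]

    @classmethod
    def from_log(cls, log: pd.DataFrame, block: str) -> "StimProtocol":
        """Build from a stimulation-log table (columns block, session,
        electrode, pulse_time_s)."""
        sub = log[log["block"] == block]
        sessions = []
        for sess, grp in sub.groupby("session"):
            sessions.append(
                StimSession(int(sess), str(grp["electrode"].iloc[0]),
                            tuple(np.sort(grp["pulse_time_s"].to_numpy(float))))
            )
        return cls(block, tuple(sorted(sessions, key=lambda s: s.session)))

    @classmethod
    def reconstruct(
        cls,
        block: str,
        stim_electrodes: Sequence[str],
        pulse_rate_hz: float = 0.2,
        session_duration_s: float = 300.0,
        start_offset_s: float = 0.0,
    ) -> "StimProtocol":
        """Reconstruct pulse times from protocol parameters when no log file
        exists (0.2 Hz, 6 electrodes, 5-min sessions -> 60 pulses/session)."""
        period = 1.0 / pulse_rate_hz
        n_pulses = int(session_duration_s * pulse_rate_hz)
        sessions = []
        for k, elec in enumerate(stim_electrodes):
            t0 = start_offset_s + k * session_duration_s
            pulses = tuple(t0 + i * period for i in range(n_pulses))
            sessions.append(StimSession(k + 1, str(elec), pulses))
        return cls(block, tuple(sessions))


def evoked_rate_per_pulse(
    train: np.ndarray | Sequence[float],
    pulse_time_s: float,
    window_s: float = DEFAULT_WINDOW_S,
) -> float:
    """Spike count in [pulse, pulse + window) divided by the window (Hz)."""
    t = np.asarray(train, float)
    n = np.count_nonzero((t >= pulse_time_s) & (t < pulse_time_s + window_s))
    return n / window_s


def session_evoked_rate(
    train: np.ndarray | Sequence[float],
    pulse_times_s: Sequence[float],
    duration_s: float,
    window_s: float = DEFAULT_WINDOW_S,
) -> float:
    """evMFR': mean evoked rate over the session's pulses.

    Pulses whose window would run past the recording end are skipped with a
    warning. NaN if no valid pulse remains.
    """
    valid = [p for p in pulse_times_s if p + window_s <= duration_s]
    if len(valid) < len(pulse_times_s):
        warnings.warn(
            f"skipped {len(pulse_times_s) - len(valid)} pulses whose window exceeds the recording"
        )
    if not valid:
        return math.nan
    return float(np.mean([evoked_rate_per_pulse(train, p, window_s) for p in valid]))


def normalize_evoked(
    evmfr_prime: Mapping[str, float],
    spontaneous_mfr: Mapping[str, float],
    min_rate_hz: float = DEFAULT_MIN_SPONT_RATE_HZ,
) -> tuple[dict[str, float], list[str]]:
    """evMFR_norm' = evMFR'/MFR_SA' per electrode.

    Electrodes whose spontaneous rate is below ``min_rate_hz`` are excluded
    (returned in the second element with their reason implicit).
    """
    out: dict[str, float] = {}
    excluded: list[str] = []
    for elec, ev in evmfr_prime.items():
        sa = spontaneous_mfr.get(elec, 0.0)
        if not math.isfinite(ev):
            excluded.append(elec)
        elif sa < min_rate_hz:
            excluded.append(elec)
        else:
            out[elec] = ev / sa
    return out, excluded


@dataclass(frozen=True)
class EvokedSummary:
    evmfr_norm: float
    cv: float        # sample SD / mean; NaN when mean = 0
    skewness: float  # NaN with < 3 values
    n_values: int


def well_evoked_summary(values: Sequence[float]) -> EvokedSummary:
    """Grand mean / CV / skewness over electrode-session evMFR_norm' values."""
    arr = np.asarray([v for v in values if math.isfinite(v)], float)
    if arr.size == 0:
        return EvokedSummary(math.nan, math.nan, math.nan, 0)
    mean = float(arr.mean())
    if arr.size < 2:
        return EvokedSummary(mean, math.nan, math.nan, 1)
    sd = float(arr.std(ddof=1))
    cv = sd / mean if mean != 0 else math.nan
    return EvokedSummary(mean, cv, sample_skewness(arr), arr.size)


def analyze_stim_block(
    stim_recording: Recording,
    protocol: StimProtocol,
    spont_recording: Recording,
    well_id: str,
    window_s: float = DEFAULT_WINDOW_S,
    min_rate_hz: float = DEFAULT_MIN_SPONT_RATE_HZ,
    exclude_stim_electrode: bool = True,
    session_duration_s: float = 300.0,
) -> EvokedSummary:
    """Well-level evoked summary of one STIM block.

    The spontaneous rate per electrode comes from the full spontaneous block
    immediately preceding the STIM block. The stimulating electrode's own
    channel is excluded during its session (artifact contamination) unless
    disabled.
    """
    trains = stim_recording.spikes.trains(well_id)
    spont = {
        e: t.size / spont_recording.duration_s
        for e, t in spont_recording.spikes.trains(well_id).items()
    }
    values: list[float] = []
    for sess in protocol.sessions:
        ev_prime: dict[str, float] = {}
        for elec, train in trains.items():
            if exclude_stim_electrode and elec == sess.stim_electrode:
                continue
            ev_prime[elec] = session_evoked_rate(
                train, sess.pulse_times_s, stim_recording.duration_s, window_s
            )
        normed, _ = normalize_evoked(ev_prime, spont, min_rate_hz)
        values.extend(normed.values())
    return well_evoked_summary(values)


def tet_effect(evmfr_norm_stim2: float, evmfr_norm_stim3: float) -> float:
    """X = log10(evMFR_norm@STIM3) / log10(evMFR_norm@STIM2); NaN when
    undefined (non-positive input or evMFR_norm@STIM2 exactly 1)."""
    if not (evmfr_norm_stim2 > 0 and evmfr_norm_stim3 > 0):
        return math.nan
    denom = math.log10(evmfr_norm_stim2)
    if denom == 0.0:
        return math.nan
    return math.log10(evmfr_norm_stim3) / denom


@dataclass(frozen=True)
class TetComparison:
    t: float
    dof: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    convention: str


def _pool(experiments: Sequence[tuple[float, float, int]]) -> tuple[float, float, int]:
    means = [m for m, _, _ in experiments]
    variances = [v for _, v, _ in experiments]
    n = sum(k for _, _, k in experiments)
    return float(np.mean(means)), float(np.mean(variances)), int(n)


def welch_aggregate_t(
    experiments_a: Sequence[tuple[float, float, int]],
    experiments_b: Sequence[tuple[float, float, int]],
    convention: Literal["welch", "printed"] = "welch",
) -> TetComparison:
    """Aggregate Welch t test on per-experiment (mean, variance, n) triples.

    Pooled mean = mean of per-experiment means; pooled S^2 = mean of
    per-experiment variances; n = total wells. ``convention`` selects the
    denominator terms S^2/n (standard Welch, default) or S^2/n^2 (printed
    variant); the Welch-Satterthwaite dof uses the same terms.
    """
    if not experiments_a or not experiments_b:
        raise ValueError("need at least one experiment per genotype")
    m_a, s2_a, n_a = _pool(experiments_a)
    m_b, s2_b, n_b = _pool(experiments_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 wells per genotype")
    if convention == "welch":
        va, vb = s2_a / n_a, s2_b / n_b
    elif convention == "printed":
        va, vb = s2_a / n_a**2, s2_b / n_b**2
    else:
        raise ValueError(f"unknown convention {convention!r}")
    se2 = va + vb
    t = (m_a - m_b) / math.sqrt(se2) if se2 > 0 else 0.0
    if se2 > 0:
        dof = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    else:
        dof = float(n_a + n_b - 2)
    p = 2.0 * float(sps.t.sf(abs(t), dof))
    return TetComparison(t, dof, p, m_a, m_b, n_a, n_b, convention)
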