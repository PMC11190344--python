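"""Baseline-normalized time courses for pharmacological disinhibition
experiments (e.g. bicuculline block of GABA_A receptors).

A treatment run records four 5-minute baseline units, a 10-minute
unrecorded gap after compound application, and further 5-minute units up to
one hour. Every activity parameter is expressed as percent of the mean of
the baseline units (baseline = 100%); the gap is represented as missing
units, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["NormalizedTimecourse", "baseline_normalize"]

DEFAULT_N_BASELINE_UNITS = 4


@dataclass
class NormalizedTimecourse:
    parameter: str
    baseline_value: float
    minutes: tuple[float, ...]       # unit start, minutes relative to application
    percent: tuple[float, ...]       # NaN = unrecorded unit
    raw: tuple[float, ...]

    @property
    def baseline_percent_mean(self) -> float:
        base = [p for m, p in zip(self.minutes, self.percent) if m < 0]
        return float(np.mean(base))


def baseline_normalize(
    values: Sequence[float],
    n_baseline_units: int = DEFAULT_N_BASELINE_UNITS,
    unit_duration_min: float = 5.0,
    gap_min: float = 10.0,
    parameter: str = "",
) -> NormalizedTimecourse:
    """Normalize a per-unit parameter series to its baseline mean (100%).

    ``values`` holds the leading ``n_baseline_units`` baseline units followed
    by the post-treatment units (recorded after the unrecorded gap). Unit
    start times are indexed in minutes from compound application: baseline
    units at negative minutes, post-treatment units from ``gap_min`` on.
    Raises ``ValueError`` when the baseline mean is not positive (such wells
    are excluded upstream with a reason code).
    """
    vals = np.asarray(values, float)
    if vals.size < n_baseline_units:
        raise ValueError(f"need at least {n_baseline_units} leading baseline units")
    baseline = float(np.nanmean(vals[:n_baseline_units]))
    if not baseline > 0:
        raise ValueError("baseline mean must be positive")
    minutes = [(-n_baseline_units + k) * unit_duration_min for k in range(n_baseline_units)]
    minutes += [gap_min + k * unit_duration_min for k in range(vals.size - n_baseline_units)]
    percent = 100.0 * vals / baseline
    return NormalizedTimecourse(
        parameter=parameter,
        baseline_value=baseline,
        minutes=tuple(minutes),
        percent=tuple(percent.tolist()),
        raw=tuple(vals.tolist()),
    )
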