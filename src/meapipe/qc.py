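"""Valid-well selection, longitudinal integrity censoring, and
stimulation-experiment stability/outlier filters.

Every exclusion carries a machine-readable reason code; nothing is dropped
silently. Reason codes:

* ``missing_reference`` — well has no reference-timepoint measurement
* ``too_few_active``    — fewer active electrodes than the minimum at reference
* ``lost_integrity``    — censored after the reference timepoint (both the
  >=2-channel drop AND the wMFR < 70% of reference condition held)
* ``incomplete_timeline`` — missing value somewhere in the experiment (PCA)
* ``unstable_sa``       — spontaneous activity differed between SA1 and SA2
* ``too_few_electrodes``— not enough per-electrode rates for the stability test
* ``evoked_ratio_outlier`` — STIM2/STIM1 evoked ratio outside Tukey fences
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WellStatus",
    "select_valid_wells",
    "integrity_filter",
    "pca_completeness_filter",
    "stim_stability_filter",
    "stim_outlier_filter",
]

DEFAULT_MIN_ACTIVE = 10
DEFAULT_DROP_CHANNELS = 2
DEFAULT_WMFR_FRACTION = 0.70


@dataclass
class WellStatus:
    well_id: str
    valid_at_reference: bool
    censored_from: int | None = None  # recording day (DIV); None = never censored
    reasons: list[str] = field(default_factory=list)


def select_valid_wells(
    reference_n_active: Mapping[str, int | float],
    min_active: int = DEFAULT_MIN_ACTIVE,
) -> tuple[set[str], dict[str, str]]:
    """Keep wells with at least ``min_active`` active electrodes at reference.

    ``reference_n_active`` maps well -> active-electrode count at the
    reference timepoint (NaN/missing = no reference measurement). Returns
    the kept set and a reason code per excluded well. The boundary is
    inclusive (exactly ``min_active`` is kept).
    """
    kept: set[str] = set()
    reasons: dict[str, str] = {}
    for well, n in reference_n_active.items():
        if n is None or (isinstance(n, float) and math.isnan(n)):
            reasons[well] = "missing_reference"
        elif n >= min_active:
            kept.add(well)
        else:
            reasons[well] = "too_few_active"
    return kept, reasons


def integrity_filter(
    well_timeline: pd.DataFrame,
    reference_day: int,
    drop_channels: int = DEFAULT_DROP_CHANNELS,
    wmfr_fraction: float = DEFAULT_WMFR_FRACTION,
) -> WellStatus:
    """Censor a well from the first post-reference day at which it lost
    integrity: active-channel drop >= ``drop_channels`` relative to reference
    AND wMFR < ``wmfr_fraction`` of the reference wMFR (both must hold).

    ``well_timeline`` is one well's per-day table with columns
    ``day, n_active, wmfr_hz`` (plus optionally ``well``). Days are DIVs.
    """
    tl = well_timeline.sort_values("day")
    well_id = str(tl["well"].iloc[0]) if "well" in tl.columns else ""
    ref_rows = tl[tl["day"] == reference_day]
    if ref_rows.empty:
        return WellStatus(well_id, False, reasons=["missing_reference"])
    ref_active = float(ref_rows["n_active"].iloc[0])
    ref_wmfr = float(ref_rows["wmfr_hz"].iloc[0])
    status = WellStatus(well_id, True)
    for _, row in tl[tl["day"] > reference_day].iterrows():
        channel_drop = ref_active - float(row["n_active"]) >= drop_channels
        activity_drop = float(row["wmfr_hz"]) < wmfr_fraction * ref_wmfr
        if channel_drop and activity_drop:
            status.censored_from = int(row["day"])
            status.reasons.append("lost_integrity")
            break
    return status


def pca_completeness_filter(well_timelines: pd.DataFrame,
                            value_columns: Sequence[str] | None = None) -> set[str]:
    """Wells with a complete parameter timeline (no missing value at any
    analyzed timepoint, and present at every timepoint).

    ``well_timelines`` is long-form with columns ``well, day`` plus
    parameter columns (``value_columns`` defaults to all others).
    """
    if well_timelines.empty:
        return set()
    cols = list(value_columns) if value_columns is not None else [
        c for c in well_timelines.columns if c not in ("well", "day")
    ]
    days = sorted(well_timelines["day"].unique())
    kept: set[str] = set()
    for well, grp in well_timelines.groupby("well"):
        if sorted(grp["day"].unique()) != days or len(grp) != len(days):
            continue
        if grp[cols].isna().any().any():
            continue
        kept.add(str(well))
    return kept


def stim_stability_filter(
    sa1_rates: Sequence[float],
    sa2_rates: Sequence[float],
    alpha: float = 0.05,
) -> tuple[bool, str | None]:
    """Keep a well iff Welch's t test finds no significant SA1 vs SA2 change
    in per-electrode firing rates (keep iff p >= alpha).

    Returns (keep, reason_code). Degenerate zero-variance inputs are decided
    by the means (identical blocks are kept; a shifted constant is not).
    """
    a = np.asarray(sa1_rates, float)
    b = np.asarray(sa2_rates, float)
    if a.size < 2 or b.size < 2:
        return False, "too_few_electrodes"
    if alpha <= 0:
        return True, None
    if np.var(a) == 0 and np.var(b) == 0:
        return (True, None) if a.mean() == b.mean() else (False, "unstable_sa")
    _, p = sps.ttest_ind(a, b, equal_var=False)
    if p >= alpha:
        return True, None
    return False, "unstable_sa"


def stim_outlier_filter(
    evmfr_norm_stim1: Mapping[str, float],
    evmfr_norm_stim2: Mapping[str, float],
    fence: float = 1.5,
) -> dict[str, bool]:
    """Tukey-fence outlier screen on the per-well STIM2/STIM1 evoked ratio.

    Wells whose ratio lies outside [Q1 - fence*IQR, Q3 + fence*IQR]
    (inclusive fences) are flagged for exclusion. With fewer than 4 wells
    the quartiles are unstable and the filter is skipped with a warning.
    """
    wells = [w for w in evmfr_norm_stim1 if w in evmfr_norm_stim2]
    ratios = {w: evmfr_norm_stim2[w] / evmfr_norm_stim1[w] for w in wells}
    if len(wells) < 4:
        warnings.warn("fewer than 4 wells: evoked-ratio outlier filter skipped")
        return {w: True for w in wells}
    vals = np.array([ratios[w] for w in wells])
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - fence * iqr, q3 + fence * iqr
    return {w: bool(lo <= ratios[w] <= hi) for w in wells}
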