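"""Spike-list and grouping-table I/O for multiwell-MEA recordings.

The raw input of the pipeline is a *spike list*: a CSV with one row per
detected spike carrying the spike time in seconds, a combined
``well_electrode`` label, and the spike amplitude in mV. Recordings are
acquired in consecutive 5-minute units that are concatenated into a single
:class:`Recording`. For synchrony analyses the spike list can be converted
into a binary timestamp matrix (electrodes x sample points) at the
acquisition sampling rate (default 12.5 kHz, i.e. one sample = 0.08 ms).

Conventions: times are seconds stored as float64, sample indices are
0-based, and every window is half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PlateLayout",
    "SpikeListDialect",
    "SpikeTable",
    "Recording",
    "GroupingTable",
    "CohortMap",
    "SpikeListFormatError",
    "read_spike_list",
    "write_spike_list",
    "assemble_recording",
    "to_timestamp_matrix",
    "read_grouping",
    "read_cohort_map",
    "DEFAULT_LAYOUT",
    "DEFAULT_DIALECT",
]

DEFAULT_SAMPLING_RATE_HZ = 12_500.0
DEFAULT_UNIT_DURATION_S = 300.0


class SpikeListFormatError(ValueError):
    """Raised when a spike list or grouping file violates the declared format."""


def _well_labels_48() -> tuple[str, ...]:
    return tuple(f"{row}{col}" for row in "ABCDEF" for col in range(1, 9))


def _electrode_labels_4x4() -> tuple[str, ...]:
    return tuple(f"{r}{c}" for r in range(1, 5) for c in range(1, 5))


@dataclass(frozen=True)
class PlateLayout:
    """Declared plate geometry: well labels and within-well electrode labels."""

    wells: tuple[str, ...] = field(default_factory=_well_labels_48)
    electrodes: tuple[str, ...] = field(default_factory=_electrode_labels_4x4)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)


DEFAULT_LAYOUT = PlateLayout()


@dataclass(frozen=True)
class SpikeListDialect:
    """Column names and label convention of the spike-list CSV.

    The default mirrors Axion-style spike lists ("Time (s)", "Electrode" with
    a combined ``well_electrode`` label, "Amplitude (mV)"); the exact header
    text is vendor-version dependent, hence configurable.
    """

    time_col: str = "Time (s)"
    electrode_col: str = "Electrode"
    amplitude_col: str = "Amplitude (mV)"
    label_sep: str = "_"


DEFAULT_DIALECT = SpikeListDialect()

_COLUMNS = ["time_s", "well", "electrode", "amplitude_mV"]


@dataclass
class SpikeTable:
    """Tidy per-recording spike list.

    ``df`` has columns ``time_s, well, electrode, amplitude_mV``; rows are
    sorted by time (stable, so simultaneous spikes keep electrode-label
    order from the input).
    """

    df: pd.DataFrame
    layout: PlateLayout = field(default_factory=PlateLayout)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise SpikeListFormatError(f"SpikeTable missing columns: {missing}")
        self.df = self.df[_COLUMNS].reset_index(drop=True)

    @property
    def n_spikes(self) -> int:
        return len(self.df)

    def wells(self) -> list[str]:
        return sorted(self.df["well"].unique())

    def well(self, well_id: str) -> pd.DataFrame:
        return self.df[self.df["well"] == well_id]

    def train(self, well_id: str, electrode_id: str) -> np.ndarray:
        """Sorted spike times (s) of one electrode."""
        sel = (self.df["well"] == well_id) & (self.df["electrode"] == electrode_id)
        return np.sort(self.df.loc[sel, "time_s"].to_numpy(float))

    def trains(self, well_id: str) -> dict[str, np.ndarray]:
        """Per-electrode sorted spike trains for one well (all layout electrodes)."""
        out = {e: np.empty(0) for e in self.layout.electrodes}
        for elec, grp in self.well(well_id).groupby("electrode", sort=False):
            out[str(elec)] = np.sort(grp["time_s"].to_numpy(float))
        return out


def empty_spike_table(layout: PlateLayout = DEFAULT_LAYOUT) -> SpikeTable:
    df = pd.DataFrame({c: pd.Series(dtype=(object if c in ("well", "electrode") else float))
                       for c in _COLUMNS})
    return SpikeTable(df, layout)


def spike_table_from_arrays(
    time_s: Sequence[float],
    well: Sequence[str],
    electrode: Sequence[str],
    amplitude_mV: Sequence[float] | None = None,
    layout: PlateLayout = DEFAULT_LAYOUT,
) -> SpikeTable:
    time = np.asarray(time_s, float)
    if time.size and time.min() < 0:
        raise SpikeListFormatError("negative spike time")
    amp = np.zeros_like(time) if amplitude_mV is None else np.asarray(amplitude_mV, float)
    df = pd.DataFrame(
        {"time_s": time, "well": list(well), "electrode": list(electrode), "amplitude_mV": amp}
    )
    _validate_labels(df, layout)
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    return SpikeTable(df, layout)


def _validate_labels(df: pd.DataFrame, layout: PlateLayout) -> None:
    bad_wells = sorted(set(df["well"]) - set(layout.wells))
    if bad_wells:
        raise SpikeListFormatError(f"well labels outside declared plate layout: {bad_wells}")
    bad_elec = sorted(set(df["electrode"]) - set(layout.electrodes))
    if bad_elec:
        raise SpikeListFormatError(f"electrode labels outside declared layout: {bad_elec}")


def read_spike_list(
    path: str | Path,
    dialect: SpikeListDialect = DEFAULT_DIALECT,
    layout: PlateLayout = DEFAULT_LAYOUT,
) -> SpikeTable:
    """Read a spike-list CSV into a :class:`SpikeTable`.

    Unknown electrode/well labels and negative times are rejected with a
    :class:`SpikeListFormatError` naming the offending value/column.
    """
    raw = pd.read_csv(path)
    for col in (dialect.time_col, dialect.electrode_col, dialect.amplitude_col):
        if col not in raw.columns:
            raise SpikeListFormatError(f"spike list {path} missing required column {col!r}")
    if raw.empty:
        return empty_spike_table(layout)
    labels = raw[dialect.electrode_col].astype(str)
    parts = labels.str.split(dialect.label_sep, n=1, expand=True)
    if parts.shape[1] < 2 or parts.isna().any().any():
        bad = labels[parts.isna().any(axis=1)].tolist() if parts.shape[1] > 1 else labels.tolist()
        raise SpikeListFormatError(
            f"electrode labels not in 'well{dialect.label_sep}electrode' form: {bad[:5]}"
        )
    return spike_table_from_arrays(
        raw[dialect.time_col].to_numpy(float),
        parts[0].tolist(),
        parts[1].tolist(),
        raw[dialect.amplitude_col].to_numpy(float),
        layout,
    )


def write_spike_list(
    table: SpikeTable,
    path: str | Path,
    dialect: SpikeListDialect = DEFAULT_DIALECT,
) -> None:
    """Write a :class:`SpikeTable` back to the spike-list CSV dialect."""
    out = pd.DataFrame(
        {
            dialect.time_col: table.df["time_s"].to_numpy(),
            dialect.electrode_col: table.df["well"].astype(str)
            + dialect.label_sep
            + table.df["electrode"].astype(str),
            dialect.amplitude_col: table.df["amplitude_mV"].to_numpy(),
        }
    )
    out.to_csv(path, index=False, float_format="%.9f")


@dataclass
class Recording:
    """Concatenated multi-unit recording of one plate.

    ``unit_boundaries_s`` holds the start offset of each 5-min unit; spikes
    exactly on a boundary belong to the later unit (half-open units).
    """

    spikes: SpikeTable
    duration_s: float
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    unit_boundaries_s: tuple[float, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def layout(self) -> PlateLayout:
        return self.spikes.layout

    def wells(self) -> list[str]:
        return self.spikes.wells()

    def split_wells(self) -> dict[str, "Recording"]:
        """One-pass split into per-well sub-recordings (same time axis).

        Avoids rescanning the full spike table for every well when a plate
        is analyzed well by well.
        """
        out = {}
        for well, grp in self.spikes.df.groupby("well", sort=True):
            out[str(well)] = Recording(
                SpikeTable(grp.reset_index(drop=True), self.layout),
                duration_s=self.duration_s,
                sampling_rate_hz=self.sampling_rate_hz,
                unit_boundaries_s=self.unit_boundaries_s,
                metadata=dict(self.metadata),
            )
        return out

    def restrict(self, t0: float, t1: float) -> "Recording":
        """Sub-recording on [t0, t1), times re-referenced to t0."""
        df = self.spikes.df
        sel = (df["time_s"] >= t0) & (df["time_s"] < t1)
        sub = df[sel].copy()
        sub["time_s"] = sub["time_s"] - t0
        return Recording(
            SpikeTable(sub.reset_index(drop=True), self.layout),
            duration_s=t1 - t0,
            sampling_rate_hz=self.sampling_rate_hz,
            metadata=dict(self.metadata),
        )


def assemble_recording(
    spike_tables: Sequence[SpikeTable],
    unit_duration_s: float = DEFAULT_UNIT_DURATION_S,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    metadata: Mapping | None = None,
) -> Recording:
    """Concatenate 5-min units into one recording with time offsets k*unit.

    Raises ``ValueError`` if any unit contains a time >= ``unit_duration_s``.
    """
    if not spike_tables:
        raise ValueError("need at least one unit")
    layout = spike_tables[0].layout
    frames = []
    for k, tab in enumerate(spike_tables):
        t = tab.df["time_s"].to_numpy(float)
        if t.size and t.max() >= unit_duration_s:
            raise ValueError(
                f"unit {k} contains spike time {t.max():.6f} s >= unit duration {unit_duration_s} s"
            )
        df = tab.df.copy()
        df["time_s"] = df["time_s"] + k * unit_duration_s
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True).sort_values("time_s", kind="stable")
    rec = Recording(
        SpikeTable(merged.reset_index(drop=True), layout),
        duration_s=len(spike_tables) * unit_duration_s,
        sampling_rate_hz=sampling_rate_hz,
        unit_boundaries_s=tuple(k * unit_duration_s for k in range(len(spike_tables))),
        metadata=dict(metadata or {}),
    )
    return rec


def sample_index(time_s, sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ):
    """0-based sample index of a spike time: floor(t * rate).

    A relative guard of 1e-6 sample absorbs float rounding of on-grid times
    (e.g. 0.00008 s at 12.5 kHz is exactly sample 1).
    """
    return np.floor(np.asarray(time_s, float) * sampling_rate_hz + 1e-6).astype(np.int64)


def to_timestamp_matrix(recording: Recording, well_id: str) -> sparse.csr_matrix:
    """Binary timestamp matrix (electrodes x samples) of one well.

    Multiple spikes mapping to one sample collapse to a single 1 (counts
    stay available in the SpikeTable). An absent well yields an empty matrix
    of the declared shape with a warning.
    """
    layout = recording.layout
    n_samples = int(round(recording.duration_s * recording.sampling_rate_hz))
    shape = (layout.n_electrodes, n_samples)
    sub = recording.spikes.well(well_id)
    if sub.empty:
        if well_id not in set(recording.wells()):
            warnings.warn(f"well {well_id} absent from recording; returning empty matrix")
        return sparse.csr_matrix(shape, dtype=np.int8)
    elec_index = {e: i for i, e in enumerate(layout.electrodes)}
    rows = sub["electrode"].map(elec_index).to_numpy()
    cols = sample_index(sub["time_s"].to_numpy(), recording.sampling_rate_hz)
    cols = np.minimum(cols, n_samples - 1)
    data = np.ones(len(rows), dtype=np.int8)
    mat = sparse.csr_matrix((data, (rows, cols)), shape=shape, dtype=np.int8)
    mat.data[:] = 1  # collapse duplicates
    return mat


@dataclass
class GroupingTable:
    """Well -> {genotype, animal, plate, include} mapping."""

    df: pd.DataFrame  # index: well; columns: genotype, animal, plate, include

    REQUIRED = ("genotype",)

    def genotype_of(self, well_id: str) -> str:
        return str(self.df.loc[well_id, "genotype"])

    def animal_of(self, well_id: str) -> str:
        return str(self.df.loc[well_id, "animal"])

    @property
    def wells(self) -> list[str]:
        return list(self.df.index)

    def included_wells(self) -> list[str]:
        if "include" in self.df.columns:
            return list(self.df.index[self.df["include"].astype(bool)])
        return list(self.df.index)

    def split_grouped(self, wells: Iterable[str]) -> tuple[list[str], list[str]]:
        """Partition wells into (grouped, ungrouped); ungrouped are excluded downstream."""
        known = set(self.wells)
        grouped = [w for w in wells if w in known]
        ungrouped = [w for w in wells if w not in known]
        if ungrouped:
            warnings.warn(f"wells missing from grouping table, excluded: {ungrouped}")
        return grouped, ungrouped


def grouping_from_frame(df: pd.DataFrame) -> GroupingTable:
    if "well" not in df.columns:
        raise SpikeListFormatError("grouping table missing 'well' column")
    if "genotype" not in df.columns:
        raise SpikeListFormatError("grouping table missing 'genotype' column")
    dup = df["well"][df["well"].duplicated()].tolist()
    if dup:
        raise SpikeListFormatError(f"duplicate wells in grouping table: {sorted(set(dup))}")
    out = df.set_index("well")
    if "animal" not in out.columns:
        out["animal"] = "NA"
    if "plate" not in out.columns:
        out["plate"] = "P1"
    return GroupingTable(out)


def read_grouping(path: str | Path) -> GroupingTable:
    """Read the well->group mapping from CSV or XLSX (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return grouping_from_frame(df)


@dataclass
class CohortMap:
    """DIV -> age-cohort label mapping with non-overlapping bins."""

    bins: dict[int, str]  # explicit DIV -> label

    @classmethod
    def from_ranges(cls, ranges: Mapping[str, tuple[int, int]]) -> "CohortMap":
        bins: dict[int, str] = {}
        for label, (lo, hi) in ranges.items():
            for div in range(lo, hi + 1):
                if div in bins:
                    raise ValueError(f"overlapping cohort bins at DIV {div}")
                bins[div] = label
        return cls(bins)

    def cohort_of(self, div: int) -> str | None:
        return self.bins.get(int(div))

    def labels(self) -> list[str]:
        seen: list[str] = []
        for div in sorted(self.bins):
            if self.bins[div] not in seen:
                seen.append(self.bins[div])
        return seen


def read_cohort_map(path: str | Path) -> CohortMap:
    """Read a DIV->cohort table (columns: div, cohort)."""
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not {"div", "cohort"} <= set(df.columns):
        raise SpikeListFormatError("cohort map needs columns 'div' and 'cohort'")
    if df["div"].duplicated().any():
        raise SpikeListFormatError("duplicate DIV rows in cohort map")
    return CohortMap({int(d): str(c) for d, c in zip(df["div"], df["cohort"])})
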