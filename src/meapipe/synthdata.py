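"""Synthetic multiwell-MEA datasets with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without recorded data:

* per-electrode homogeneous Poisson background whose rate follows a
  developmental trajectory (rising from DIV 10 to a mature plateau);
* superimposed single-electrode bursts (Poisson event process, each event
  >= 5 spikes with intra-burst ISIs < 100 ms);
* superimposed network-burst events recruiting K random channels with a
  tight pooled spike packet (>= 50 spikes, pooled ISIs far below 100 ms);
* a genotype effect gamma(DIV) multiplying background and NB rates
  (gamma > 1 early, fading to 1 with maturation — early hyperactivity that
  converges as networks mature);
* persistent lognormal well-to-well rate heterogeneity plus per-day jitter;
* electrode dropout modeled as sub-threshold noise firing (< 0.1 Hz), so
  active-electrode counting is exercised;
* evoked datasets in which each 1 s post-pulse window multiplies the rate
  by a gain g (g' after tetanus).

Everything is a pure function of (config, seed); identical inputs give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spikeio import (
    PlateLayout,
    Recording,
    SpikeTable,
    GroupingTable,
    grouping_from_frame,
    spike_table_from_arrays,
    write_spike_list,
    DEFAULT_SAMPLING_RATE_HZ,
)

__all__ = [
    "GeneratorConfig",
    "StimGeneratorConfig",
    "DisinhibitionGeneratorConfig",
    "DevelopmentDataset",
    "StimDataset",
    "DisinhibitionDataset",
    "generate_development_dataset",
    "generate_stim_dataset",
    "generate_disinhibition_dataset",
]


def _interp(traj: Mapping[int, float], div: float) -> float:
    xs = np.array(sorted(traj))
    ys = np.array([traj[k] for k in xs])
    return float(np.interp(div, xs, ys))


def _electrodes_4x4() -> tuple[str, ...]:
    return tuple(f"{r}{c}" for r in range(1, 5) for c in range(1, 5))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a longitudinal development experiment.

    Rates are piecewise-linear trajectories over DIV. ``genotype_gamma``
    multiplies background and NB rates for the mutant genotype (1.5 up to
    DIV 20, fading to 1.0 at DIV 24 and beyond).
    """

    n_wells_per_genotype: int = 20
    genotypes: tuple[str, str] = ("control", "mutant")
    wells_per_animal: int = 4
    div_schedule: tuple[int, ...] = (11, 15, 17, 19, 21, 24, 30, 33)
    n_units: int = 4
    unit_duration_s: float = 300.0
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    background_rate_hz: Mapping[int, float] = field(
        default_factory=lambda: {10: 0.3, 15: 0.8, 20: 1.5, 25: 2.0, 33: 2.0}
    )
    burst_rate_per_min: Mapping[int, float] = field(
        default_factory=lambda: {10: 0.5, 15: 1.5, 20: 2.5, 25: 3.0, 33: 3.0}
    )
    nb_rate_per_min: Mapping[int, float] = field(
        default_factory=lambda: {10: 0.3, 15: 1.0, 20: 2.0, 25: 3.0, 33: 3.0}
    )
    nb_channels: Mapping[int, float] = field(
        default_factory=lambda: {10: 5, 15: 8, 20: 10, 25: 12, 33: 12}
    )
    nb_min_total_spikes: int = 55
    burst_spikes_mean: float = 8.0
    genotype_gamma: Mapping[int, float] = field(
        default_factory=lambda: {10: 1.5, 20: 1.5, 24: 1.0, 33: 1.0}
    )
    well_sd_log10: float = 0.15
    div_jitter_log10: float = 0.05
    dropout_prob: float = 0.02
    dropout_rate_hz: float = 0.05
    amplitude_mean_mV: float = 0.03
    amplitude_sd_mV: float = 0.01

    def gamma(self, genotype: str, div: float) -> float:
        if genotype == self.genotypes[0]:
            return 1.0
        return _interp(self.genotype_gamma, div)


def _make_layout(n_wells: int) -> tuple[PlateLayout, list[str], list[str]]:
    """Well labels across as many 48-well plates as needed."""
    base = [f"{row}{col}" for row in "ABCDEF" for col in range(1, 9)]
    wells: list[str] = []
    plates: list[str] = []
    k = 0
    while len(wells) < n_wells:
        plate = f"P{k + 1}"
        for w in base:
            if len(wells) >= n_wells:
                break
            wells.append(w if k == 0 else f"{plate}-{w}")
            plates.append(plate)
        k += 1
    return PlateLayout(wells=tuple(wells), electrodes=_electrodes_4x4()), wells, plates


def _grouping(cfg_wells: list[str], plates: list[str], genotypes: Sequence[str],
              n_per: int, wells_per_animal: int) -> GroupingTable:
    rows = []
    for i, (w, p) in enumerate(zip(cfg_wells, plates)):
        g = genotypes[0] if i < n_per else genotypes[1]
        local = i if i < n_per else i - n_per
        rows.append(
            {"well": w, "genotype": g, "animal": f"{g}-a{local // wells_per_animal + 1}",
             "plate": p}
        )
    return grouping_from_frame(pd.DataFrame(rows))


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, n))


def _burst_packet(rng: np.random.Generator, onset: float, n_spikes: int) -> np.ndarray:
    # intra-burst ISIs strictly below the 100 ms detection threshold
    isis = rng.uniform(0.002, 0.090, n_spikes - 1)
    return onset + np.concatenate(([0.0], np.cumsum(isis)))


@dataclass
class WellTruth:
    lam: float
    nu_per_min: float
    k_channels: int
    gamma: float
    dropout: list[str]


@dataclass
class DevelopmentDataset:
    recordings: dict[int, Recording]  # DIV -> recording
    grouping: GroupingTable
    truth: dict[int, dict[str, WellTruth]]  # DIV -> well -> truth
    config: GeneratorConfig
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for div, rec in sorted(self.recordings.items()):
            write_spike_list(rec.spikes, out / f"spikes_DIV{div:02d}.csv")
        gdf = self.grouping.df.reset_index()
        gdf.to_csv(out / "grouping.csv", index=False)
        truth = {
            str(div): {w: asdict(t) for w, t in wells.items()}
            for div, wells in self.truth.items()
        }
        (out / "ground_truth.json").write_text(
            json.dumps({"seed": self.seed, "truth": truth}, indent=1, sort_keys=True)
        )


def _simulate_well(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    lam: float,
    burst_rate_min: float,
    nu_min: float,
    k_channels: int,
    duration: float,
    electrodes: tuple[str, ...],
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Spike trains per electrode for one well on one day."""
    trains: dict[str, list[np.ndarray]] = {e: [] for e in electrodes}
    dropout = [e for e in electrodes if rng.random() < cfg.dropout_prob]
    for e in electrodes:
        if e in dropout:
            trains[e].append(_poisson_times(rng, cfg.dropout_rate_hz, duration))
            continue
        trains[e].append(_poisson_times(rng, lam, duration))
        n_bursts = rng.poisson(burst_rate_min * duration / 60.0)
        for onset in rng.uniform(0.0, duration - 1.0, n_bursts):
            m = 5 + rng.poisson(max(cfg.burst_spikes_mean - 5.0, 0.0))
            trains[e].append(_burst_packet(rng, onset, m))
    live = [e for e in electrodes if e not in dropout]
    k = min(k_channels, len(live))
    if k >= 1:
        n_nbs = rng.poisson(nu_min * duration / 60.0)
        for onset in rng.uniform(0.0, duration - 2.0, n_nbs):
            chans = rng.choice(live, size=k, replace=False)
            base = int(np.ceil(cfg.nb_min_total_spikes / k))
            counts = base + rng.poisson(2.0, k)
            seq = rng.permutation(np.repeat(chans, counts))
            gaps = rng.uniform(0.001, 0.004, seq.size - 1)
            times = onset + np.concatenate(([0.0], np.cumsum(gaps)))
            for e in chans:
                trains[e].append(times[seq == e])
    out = {}
    for e in electrodes:
        t = np.sort(np.concatenate(trains[e])) if trains[e] else np.empty(0)
        out[e] = t[t < duration]
    return out, dropout


def _to_recording(
    well_trains: Mapping[str, Mapping[str, np.ndarray]],
    layout: PlateLayout,
    duration: float,
    cfg_amp_mean: float,
    cfg_amp_sd: float,
    rng: np.random.Generator,
    n_units: int,
    unit_duration_s: float,
    sampling_rate_hz: float,
    metadata: dict,
) -> Recording:
    times, wells, elecs = [], [], []
    for w in layout.wells:
        if w not in well_trains:
            continue
        for e in layout.electrodes:
            t = well_trains[w][e]
            times.append(t)
            wells.extend([w] * t.size)
            elecs.extend([e] * t.size)
    all_t = np.concatenate(times) if times else np.empty(0)
    amp = np.abs(rng.normal(cfg_amp_mean, cfg_amp_sd, all_t.size))
    table = spike_table_from_arrays(all_t, wells, elecs, amp, layout)
    return Recording(
        table,
        duration_s=duration,
        sampling_rate_hz=sampling_rate_hz,
        unit_boundaries_s=tuple(k * unit_duration_s for k in range(n_units)),
        metadata=metadata,
    )


def generate_development_dataset(
    config: GeneratorConfig | None = None, seed: int = 0
) -> DevelopmentDataset:
    """Longitudinal two-genotype dataset over the configured DIV schedule."""
    cfg = config or GeneratorConfig()
    n_total = 2 * cfg.n_wells_per_genotype
    layout, wells, plates = _make_layout(n_total)
    grouping = _grouping(wells, plates, cfg.genotypes, cfg.n_wells_per_genotype,
                         cfg.wells_per_animal)
    duration = cfg.n_units * cfg.unit_duration_s
    # persistent per-well heterogeneity (shared across DIVs)
    well_rng = np.random.default_rng([seed, 7919])
    well_factor = {w: 10 ** (well_rng.normal(0.0, cfg.well_sd_log10)) for w in wells}
    recordings: dict[int, Recording] = {}
    truth: dict[int, dict[str, WellTruth]] = {}
    for div in cfg.div_schedule:
        day_truth: dict[str, WellTruth] = {}
        day_trains: dict[str, dict[str, np.ndarray]] = {}
        for wi, w in enumerate(wells):
            rng = np.random.default_rng([seed, int(div), wi])
            genotype = grouping.genotype_of(w)
            gamma = cfg.gamma(genotype, div)
            jitter = 10 ** (rng.normal(0.0, cfg.div_jitter_log10))
            lam = _interp(cfg.background_rate_hz, div) * gamma * well_factor[w] * jitter
            nu = _interp(cfg.nb_rate_per_min, div) * gamma * well_factor[w] * jitter
            burst_rate = _interp(cfg.burst_rate_per_min, div) * well_factor[w]
            k_channels = int(round(_interp(cfg.nb_channels, div)))
            trains, dropout = _simulate_well(
                rng, cfg, lam, burst_rate, nu, k_channels, duration, layout.electrodes
            )
            day_trains[w] = trains
            day_truth[w] = WellTruth(lam, nu, k_channels, gamma, dropout)
        amp_rng = np.random.default_rng([seed, int(div), 999_983])
        recordings[div] = _to_recording(
            day_trains, layout, duration, cfg.amplitude_mean_mV, cfg.amplitude_sd_mV,
            amp_rng, cfg.n_units, cfg.unit_duration_s, cfg.sampling_rate_hz,
            {"DIV": int(div)},
        )
        truth[div] = day_truth
    return DevelopmentDataset(recordings, grouping, truth, cfg, seed)


# ---------------------------------------------------------------------------
# evoked / tetanus datasets


@dataclass(frozen=True)
class StimGeneratorConfig:
    """Study conditions of an electrical-stimulation experiment.

    ``evoked_gain`` multiplies the firing rate inside each 1 s post-pulse
    window during STIM1/STIM2; ``post_tet_gain`` applies during STIM3.
    Equal gains mean the tetanus had no effect (X = 1).
    """

    n_wells_per_genotype: int = 8
    genotypes: tuple[str, str] = ("control", "mutant")
    wells_per_animal: int = 4
    background_rate_hz: float = 2.0
    well_sd_log10: float = 0.10
    evoked_gain: Mapping[str, float] = field(
        default_factory=lambda: {"control": 3.0, "mutant": 3.0}
    )
    post_tet_gain: Mapping[str, float] = field(
        default_factory=lambda: {"control": 3.0, "mutant": 4.5}
    )
    gain_jitter_log10: float = 0.03
    stim_electrodes: tuple[str, ...] = ("11", "14", "22", "33", "41", "44")
    tet_electrode: str = "22"
    pulse_rate_hz: float = 0.2
    n_sessions: int = 6
    session_duration_s: float = 300.0
    sa1_duration_s: float = 1200.0
    sa_mid_duration_s: float = 600.0
    window_s: float = 1.0
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    amplitude_mean_mV: float = 0.03
    amplitude_sd_mV: float = 0.01


@dataclass
class StimDataset:
    blocks: dict[str, Recording]  # SA1, STIM1, SA2, STIM2, TET, SA3, STIM3
    stim_log: pd.DataFrame        # block, session, electrode, pulse_time_s
    grouping: GroupingTable
    truth: dict[str, dict[str, float]]  # well -> {lam, gain, post_tet_gain}
    config: StimGeneratorConfig
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for block, rec in self.blocks.items():
            write_spike_list(rec.spikes, out / f"spikes_{block}.csv")
        self.stim_log.to_csv(out / "stim_log.csv", index=False)
        self.grouping.df.reset_index().to_csv(out / "grouping.csv", index=False)
        (out / "ground_truth.json").write_text(
            json.dumps({"seed": self.seed, "truth": self.truth}, indent=1, sort_keys=True)
        )


def _stim_block_pulses(cfg: StimGeneratorConfig) -> list[tuple[int, str, np.ndarray]]:
    period = 1.0 / cfg.pulse_rate_hz
    n_pulses = int(cfg.session_duration_s * cfg.pulse_rate_hz)
    out = []
    for k, elec in enumerate(cfg.stim_electrodes[: cfg.n_sessions]):
        t0 = k * cfg.session_duration_s
        out.append((k + 1, elec, t0 + np.arange(n_pulses) * period))
    return out


def _evoked_block_trains(
    rng: np.random.Generator,
    lam: float,
    gain: float,
    pulses: np.ndarray,
    duration: float,
    window: float,
    electrodes: tuple[str, ...],
) -> dict[str, np.ndarray]:
    trains = {}
    for e in electrodes:
        t = _poisson_times(rng, lam, duration)
        if gain > 1.0:
            extra = []
            n_extra = rng.poisson((gain - 1.0) * lam * window, pulses.size)
            for p, n in zip(pulses, n_extra):
                if n:
                    extra.append(p + rng.uniform(0.0, window, n))
            if extra:
                t = np.sort(np.concatenate([t] + extra))
        trains[e] = t[t < duration]
    return trains


def generate_stim_dataset(
    config: StimGeneratorConfig | None = None, seed: int = 0
) -> StimDataset:
    """Evoked-activity dataset: SA and STIM blocks plus a stimulation log."""
    cfg = config or StimGeneratorConfig()
    n_total = 2 * cfg.n_wells_per_genotype
    layout, wells, plates = _make_layout(n_total)
    grouping = _grouping(wells, plates, cfg.genotypes, cfg.n_wells_per_genotype,
                         cfg.wells_per_animal)
    stim_dur = cfg.n_sessions * cfg.session_duration_s
    tet_dur = 100.0  # 20 bursts at 0.2 Hz
    block_plan = [
        ("SA1", cfg.sa1_duration_s), ("STIM1", stim_dur), ("SA2", cfg.sa_mid_duration_s),
        ("STIM2", stim_dur), ("TET", tet_dur), ("SA3", cfg.sa_mid_duration_s),
        ("STIM3", stim_dur),
    ]
    pulses_per_session = _stim_block_pulses(cfg)
    all_pulses = np.concatenate([p for _, _, p in pulses_per_session])
    well_rng = np.random.default_rng([seed, 104_729])
    truth: dict[str, dict[str, float]] = {}
    lam_w, gain_w, tet_gain_w = {}, {}, {}
    for w in wells:
        genotype = grouping.genotype_of(w)
        lam_w[w] = cfg.background_rate_hz * 10 ** (well_rng.normal(0.0, cfg.well_sd_log10))
        gain_w[w] = cfg.evoked_gain[genotype] * 10 ** (
            well_rng.normal(0.0, cfg.gain_jitter_log10)
        )
        tet_gain_w[w] = cfg.post_tet_gain[genotype] * 10 ** (
            well_rng.normal(0.0, cfg.gain_jitter_log10)
        )
        truth[w] = {"lam": lam_w[w], "gain": gain_w[w], "post_tet_gain": tet_gain_w[w]}
    blocks: dict[str, Recording] = {}
    for bi, (block, dur) in enumerate(block_plan):
        day_trains: dict[str, dict[str, np.ndarray]] = {}
        for wi, w in enumerate(wells):
            rng = np.random.default_rng([seed, bi, wi])
            if block.startswith("SA") or block == "TET":
                trains = {e: _poisson_times(rng, lam_w[w], dur) for e in layout.electrodes}
            else:
                g = tet_gain_w[w] if block == "STIM3" else gain_w[w]
                trains = _evoked_block_trains(
                    rng, lam_w[w], g, all_pulses, dur, cfg.window_s, layout.electrodes
                )
            day_trains[w] = trains
        amp_rng = np.random.default_rng([seed, bi, 999_983])
        blocks[block] = _to_recording(
            day_trains, layout, dur, cfg.amplitude_mean_mV, cfg.amplitude_sd_mV,
            amp_rng, 1, dur, cfg.sampling_rate_hz, {"block": block},
        )
    log_rows = []
    for block in ("STIM1", "STIM2", "STIM3"):
        for sess, elec, pulses in pulses_per_session:
            for p in pulses:
                log_rows.append(
                    {"block": block, "session": sess, "electrode": elec, "pulse_time_s": p}
                )
    stim_log = pd.DataFrame(log_rows)
    return StimDataset(blocks, stim_log, grouping, truth, cfg, seed)


# ---------------------------------------------------------------------------
# disinhibition (baseline / post-treatment step gain) datasets


@dataclass(frozen=True)
class DisinhibitionGeneratorConfig:
    """Baseline + post-treatment recording with a step gain after application."""

    n_wells_per_genotype: int = 8
    genotypes: tuple[str, str] = ("control", "mutant")
    wells_per_animal: int = 4
    background_rate_hz: float = 2.0
    nb_rate_per_min: float = 2.0
    nb_channels: int = 10
    nb_min_total_spikes: int = 55
    well_sd_log10: float = 0.10
    treatment_gain: Mapping[str, float] = field(
        default_factory=lambda: {"control": 2.0, "mutant": 2.0}
    )
    n_baseline_units: int = 4
    n_post_units: int = 10
    unit_duration_s: float = 300.0
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    amplitude_mean_mV: float = 0.03
    amplitude_sd_mV: float = 0.01


@dataclass
class DisinhibitionDataset:
    baseline: Recording
    post: Recording
    grouping: GroupingTable
    truth: dict[str, dict[str, float]]
    config: DisinhibitionGeneratorConfig
    seed: int


def generate_disinhibition_dataset(
    config: DisinhibitionGeneratorConfig | None = None, seed: int = 0
) -> DisinhibitionDataset:
    cfg = config or DisinhibitionGeneratorConfig()
    n_total = 2 * cfg.n_wells_per_genotype
    layout, wells, plates = _make_layout(n_total)
    grouping = _grouping(wells, plates, cfg.genotypes, cfg.n_wells_per_genotype,
                         cfg.wells_per_animal)
    well_rng = np.random.default_rng([seed, 15_485_863])
    lam_w = {
        w: cfg.background_rate_hz * 10 ** (well_rng.normal(0.0, cfg.well_sd_log10))
        for w in wells
    }
    truth = {
        w: {"lam": lam_w[w], "gain": cfg.treatment_gain[grouping.genotype_of(w)]}
        for w in wells
    }
    gen_cfg = GeneratorConfig(nb_min_total_spikes=cfg.nb_min_total_spikes)

    def _phase(phase_id: int, n_units: int, gain_map) -> Recording:
        dur = n_units * cfg.unit_duration_s
        day_trains = {}
        for wi, w in enumerate(wells):
            rng = np.random.default_rng([seed, phase_id, wi])
            g = gain_map(w)
            trains, _ = _simulate_well(
                rng, gen_cfg, lam_w[w] * g, 0.0, cfg.nb_rate_per_min * g,
                cfg.nb_channels, dur, layout.electrodes,
            )
            day_trains[w] = trains
        amp_rng = np.random.default_rng([seed, phase_id, 999_983])
        return _to_recording(
            day_trains, layout, dur, cfg.amplitude_mean_mV, cfg.amplitude_sd_mV,
            amp_rng, n_units, cfg.unit_duration_s, cfg.sampling_rate_hz,
            {"phase": "baseline" if phase_id == 0 else "post"},
        )

    baseline = _phase(0, cfg.n_baseline_units, lambda w: 1.0)
    post = _phase(1, cfg.n_post_units, lambda w: truth[w]["gain"])
    return DisinhibitionDataset(baseline, post, grouping, truth, cfg, seed)
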