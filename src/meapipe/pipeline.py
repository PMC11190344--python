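"""Batch orchestration of the three experiment types plus a thin CLI.

``run_timeseries`` reproduces the longitudinal spontaneous-activity
analysis: per-well metrics per recording day -> QC (activity selection at
the reference timepoint, integrity censoring) -> well- and
preparation-level grouping -> per-cohort PCA with Mahalanobis/Hotelling
cluster separation and feature-specific PC1 projections -> per-parameter
tests. ``run_disinhibition`` produces baseline-normalized time courses,
``run_stim`` the evoked-activity / tetanus analysis.

All thresholds live in :class:`RunConfig` and are embedded in the emitted
provenance record; outputs are plain CSV + JSON and deterministic given
inputs and config.
"""

from __future__ import annotations

import argparse
import json
import math
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .spikeio import (
    CohortMap,
    GroupingTable,
    Recording,
    read_grouping,
    read_spike_list,
    assemble_recording,
)
from . import metrics as _metrics
from . import network as _network
from . import qc as _qc
from . import pca as _pca
from . import evoked as _evoked
from . import treatment as _treatment
from . import stats as _stats
from . import synthdata as _synth

__all__ = [
    "RunConfig",
    "compute_well_metrics",
    "compute_metrics_table",
    "TimeseriesResult",
    "run_timeseries",
    "run_disinhibition",
    "run_stim",
    "aggregate_tet_experiments",
    "main",
]

#: canonical column order of the well-metrics table
METRIC_COLUMNS = [
    "n_active_electrodes", "mfr_hz", "wmfr_hz", "wtmfr_hz", "mean_isi_s",
    "mbr_hz", "wmbr_hz", "mean_burst_duration_s", "mean_spikes_per_burst",
    "pct_spikes_in_bursts", "n_network_bursts", "mean_nb_duration_s",
    "mean_spikes_per_nb", "mean_channels_per_nb", "nb_rate_hz",
    "mean_sttc", "skewness_sttc", "pct_spikes_in_nbs", "mean_inter_nb_interval_s",
]


@dataclass
class RunConfig:
    """Every analysis threshold, explicit (no hidden defaults in outputs)."""

    min_rate_hz: float = 0.1
    min_active: int = 10
    min_active_evoked: int = 8
    burst_max_isi_s: float = 0.100
    burst_min_spikes: int = 5
    nb_max_isi_s: float = 0.100
    nb_min_spikes: int = 50
    nb_min_channels: int = 5
    sttc_dt_s: float = 0.100
    sttc_restrict_to_nb: bool = False
    integrity_drop_channels: int = 2
    integrity_wmfr_fraction: float = 0.70
    alpha: float = 0.05
    outlier_fence: float = 1.5
    wmfr_weighting: str = "scale_up"
    wmbr_weighting: str = "scale_down"
    pca_preset: str = "full_19"
    reference_window: tuple[int, int] = (21, 24)
    welch_convention: str = "welch"
    evoked_window_s: float = 1.0
    exclude_stim_electrode: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference_window"] = list(self.reference_window)
        return d

    def provenance(self) -> dict:
        import scipy
        import sklearn

        return {
            "config": self.to_dict(),
            "versions": {
                "meapipe": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }


def compute_well_metrics(
    recording: Recording,
    well_id: str,
    e_max: int | None = None,
    config: RunConfig | None = None,
) -> dict:
    """One well's full spontaneous-activity parameter record."""
    cfg = config or RunConfig()
    dur = recording.duration_s
    sub = recording.spikes.well(well_id)
    trains = recording.spikes.trains(well_id)
    sm = _metrics.spike_metrics_from_trains(
        trains, dur, e_max=e_max, min_rate_hz=cfg.min_rate_hz,
        e_total=recording.layout.n_electrodes, weighting=cfg.wmfr_weighting,
    )
    bursts: list[_metrics.Burst] = []
    for elec, train in trains.items():
        bursts.extend(
            _metrics.detect_bursts(train, cfg.burst_max_isi_s, cfg.burst_min_spikes, elec)
        )
    bm = _metrics.burst_metrics_from_counts(
        bursts, dur, e_act=sm.n_active, e_max=e_max, weighting=cfg.wmbr_weighting
    )
    n_total = len(sub)
    in_bursts = sum(b.n_spikes for b in bursts)
    nbs = _network.detect_network_bursts_pooled(
        sub["time_s"].to_numpy(float), sub["electrode"].to_numpy(str),
        cfg.nb_max_isi_s, cfg.nb_min_spikes, cfg.nb_min_channels,
    )
    nbstats = _network.nb_stats_from_counts(nbs, dur, n_total)
    sttc = _network.sttc_summary_from_trains(
        trains, dur, tuple(recording.layout.electrodes),
        dt_s=cfg.sttc_dt_s, restrict_to_nb=cfg.sttc_restrict_to_nb,
        nb_kwargs={
            "max_isi_s": cfg.nb_max_isi_s, "min_spikes": cfg.nb_min_spikes,
            "min_channels": cfg.nb_min_channels,
        },
    )
    return {
        "well": well_id,
        "n_active_electrodes": sm.n_active,
        "mfr_hz": sm.mfr_hz,
        "wmfr_hz": sm.wmfr_hz,
        "wtmfr_hz": sm.wtmfr_hz,
        "mean_isi_s": sm.mean_isi_s,
        "mbr_hz": bm.mbr_hz,
        "wmbr_hz": bm.wmbr_hz,
        "mean_burst_duration_s": bm.mean_burst_duration_s,
        "mean_spikes_per_burst": bm.mean_spikes_per_burst,
        "pct_spikes_in_bursts": 100.0 * in_bursts / n_total if n_total else math.nan,
        "n_network_bursts": nbstats.n_nbs,
        "mean_nb_duration_s": nbstats.mean_nb_duration_s,
        "mean_spikes_per_nb": nbstats.mean_spikes_per_nb,
        "mean_channels_per_nb": nbstats.mean_channels_per_nb,
        "nb_rate_hz": nbstats.nb_rate_hz,
        "mean_sttc": sttc.mean_sttc,
        "skewness_sttc": sttc.skewness_sttc,
        "pct_spikes_in_nbs": nbstats.pct_spikes_in_nbs,
        "mean_inter_nb_interval_s": nbstats.mean_inter_nb_interval_s,
        "e_max": sm.e_max,
    }


def compute_metrics_table(
    recording: Recording,
    wells: Sequence[str],
    e_max: Mapping[str, int] | None = None,
    config: RunConfig | None = None,
    day: int | None = None,
) -> pd.DataFrame:
    rows = []
    per_well = recording.split_wells()
    from .spikeio import empty_spike_table

    for w in wells:
        sub = per_well.get(w)
        if sub is None:  # silent well: no spikes anywhere
            sub = Recording(empty_spike_table(recording.layout), recording.duration_s,
                            recording.sampling_rate_hz, recording.unit_boundaries_s)
        row = compute_well_metrics(
            sub, w, e_max=None if e_max is None else e_max.get(w), config=config
        )
        if day is not None:
            row["day"] = day
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TimeseriesResult:
    well_metrics: pd.DataFrame        # long: well, day, cohort, genotype, animal, params
    prep_metrics: pd.DataFrame        # preparation-level means
    qc_report: pd.DataFrame           # well, status, reason, censored_from
    separations: pd.DataFrame         # per cohort: D, T2, F, dof, p, n, cum var PC1+2
    feature_pc1: dict[str, pd.DataFrame]
    stats_summary: pd.DataFrame       # per cohort x parameter Mann-Whitney + r
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.well_metrics.to_csv(out / "well_metrics.csv", index=False)
        self.prep_metrics.to_csv(out / "prep_metrics.csv", index=False)
        self.qc_report.to_csv(out / "qc_report.csv", index=False)
        self.separations.to_csv(out / "cluster_separation.csv", index=False)
        for preset, df in self.feature_pc1.items():
            df.to_csv(out / f"feature_pc1_{preset}.csv", index=False)
        self.stats_summary.to_csv(out / "stats_summary.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1,
                                                        sort_keys=True))


def _default_cohorts(divs: Sequence[int]) -> CohortMap:
    return CohortMap({int(d): f"DIV {d}" for d in divs})


def run_timeseries(
    recordings: Mapping[int, Recording],
    grouping: GroupingTable,
    cohorts: CohortMap | None = None,
    config: RunConfig | None = None,
) -> TimeseriesResult:
    """Longitudinal spontaneous-activity analysis of a DIV-indexed recording set."""
    cfg = config or RunConfig()
    divs = sorted(recordings)
    cohorts = cohorts or _default_cohorts(divs)
    ref_lo, ref_hi = cfg.reference_window
    ref_divs = [d for d in divs if ref_lo <= d <= ref_hi]
    if not ref_divs:
        # fall back to the latest day at or before the window, else the last day
        earlier = [d for d in divs if d < ref_lo]
        ref_divs = [earlier[-1] if earlier else divs[-1]]
    ref_day = ref_divs[-1]

    all_wells = sorted(set().union(*(set(r.wells()) for r in recordings.values())))
    wells, ungrouped = grouping.split_grouped(all_wells)

    # pass 1: active-electrode counts at the reference window -> e_max and QC
    ref_splits = {d: recordings[d].split_wells() for d in ref_divs}
    ref_active: dict[str, float] = {}
    for w in wells:
        counts = [
            len(_metrics.active_electrodes(ref_splits[d][w], w, cfg.min_rate_hz))
            for d in ref_divs
            if w in ref_splits[d]
        ]
        ref_active[w] = max(counts) if counts else math.nan
    valid, sel_reasons = _qc.select_valid_wells(ref_active, cfg.min_active)
    e_max = {w: int(ref_active[w]) for w in valid}

    # pass 2: full metrics for valid wells on every day
    frames = []
    for d in divs:
        tab = compute_metrics_table(recordings[d], sorted(valid), e_max, cfg, day=d)
        frames.append(tab)
    wm = pd.concat(frames, ignore_index=True)
    wm["cohort"] = [cohorts.cohort_of(d) for d in wm["day"]]
    wm["genotype"] = [grouping.genotype_of(w) for w in wm["well"]]
    wm["animal"] = [grouping.animal_of(w) for w in wm["well"]]

    # integrity censoring beyond the reference timepoint
    qc_rows = []
    censored_rows = []
    for w in sorted(valid):
        tl = wm[wm["well"] == w][["well", "day", "n_active_electrodes", "wmfr_hz"]]
        tl = tl.rename(columns={"n_active_electrodes": "n_active"})
        status = _qc.integrity_filter(
            tl, ref_day, cfg.integrity_drop_channels, cfg.integrity_wmfr_fraction
        )
        qc_rows.append(
            {"well": w, "status": "censored" if status.censored_from else "kept",
             "reason": ";".join(status.reasons), "censored_from": status.censored_from}
        )
        if status.censored_from is not None:
            censored_rows.append((w, status.censored_from))
    for w, day0 in censored_rows:
        wm = wm[~((wm["well"] == w) & (wm["day"] >= day0))]
    for w in sorted(set(all_wells) - valid):
        qc_rows.append(
            {"well": w, "status": "excluded",
             "reason": sel_reasons.get(w, "ungrouped"), "censored_from": None}
        )
    qc_report = pd.DataFrame(qc_rows).sort_values("well").reset_index(drop=True)

    # preparation-level means (wells averaged per animal)
    prep = (
        wm.groupby(["genotype", "animal", "day", "cohort"], dropna=False)[METRIC_COLUMNS]
        .mean()
        .reset_index()
    )

    # PCA: completeness over the whole course, then per-cohort separation
    complete = _qc.pca_completeness_filter(
        wm[["well", "day"] + METRIC_COLUMNS], METRIC_COLUMNS
    )
    spec = _pca.PRESETS[cfg.pca_preset]
    sep_rows = []
    for cohort in cohorts.labels():
        sub = wm[(wm["cohort"] == cohort) & wm["well"].isin(complete)]
        if sub.empty:
            continue
        sub = sub.copy()
        sub["obs"] = sub["well"] + "@" + sub["day"].astype(str)
        vec = _pca.build_vectors(
            sub.set_index("obs").drop(columns=["well"]), spec
        ).dropna()
        sub = sub.set_index("obs").loc[vec.index]
        labels = sub["genotype"]
        if labels.nunique() != 2 or labels.value_counts().min() < 3 or len(vec) < 6:
            continue
        z, _dropped = _pca.standardize_by_timepoint(vec, timepoint=sub["day"])
        if z.shape[1] < 2:
            continue
        res = _pca.pca_fit(z)
        sep = _pca.cluster_separation(res.scores[["PC1", "PC2"]], labels.to_numpy())
        sep_rows.append(
            {
                "cohort": cohort,
                "mahalanobis_d": sep.mahalanobis_d,
                "hotelling_t2": sep.hotelling_t2,
                "f_value": sep.f_value,
                "dof1": sep.dof[0], "dof2": sep.dof[1],
                "p_value": sep.p_value,
                "n_a": sep.n_a, "n_b": sep.n_b,
                "label_a": sep.label_a, "label_b": sep.label_b,
                "cum_var_pc12": float(res.explained_variance_ratio[:2].sum()),
            }
        )
    separations = pd.DataFrame(sep_rows)

    feature_pc1 = {}
    for preset in ("spiking_4", "bursting_3", "network_4"):
        proj = _pca.feature_pc1_projection(
            wm[wm["well"].isin(complete)], preset, cohort_col="cohort"
        )
        if not proj.empty:
            proj["genotype"] = [grouping.genotype_of(w) for w in proj["well"]]
        feature_pc1[preset] = proj

    # per-cohort, per-parameter Mann-Whitney tests with Wendt's r (well level)
    stat_rows = []
    g_a, g_b = sorted(wm["genotype"].unique())[:2] if wm["genotype"].nunique() >= 2 else (None, None)
    if g_a is not None:
        for cohort in cohorts.labels():
            sub = wm[wm["cohort"] == cohort]
            for param in METRIC_COLUMNS:
                a = sub.loc[sub["genotype"] == g_a, param].dropna()
                b = sub.loc[sub["genotype"] == g_b, param].dropna()
                if len(a) < 3 or len(b) < 3:
                    continue
                u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                r = _stats.r_wendt(float(u), len(a), len(b))
                stat_rows.append(
                    {"cohort": cohort, "parameter": param, "test": "mann_whitney",
                     "statistic": float(u), "p_value": float(p), "r": r.r,
                     "benchmark": r.benchmark, "n_a": len(a), "n_b": len(b)}
                )
    stats_summary = pd.DataFrame(stat_rows)

    return TimeseriesResult(
        well_metrics=wm.reset_index(drop=True),
        prep_metrics=prep,
        qc_report=qc_report,
        separations=separations,
        feature_pc1=feature_pc1,
        stats_summary=stats_summary,
        provenance=cfg.provenance(),
    )


@dataclass
class DisinhibitionResult:
    timecourse: pd.DataFrame  # well, genotype, parameter, minute, raw, percent
    tests: pd.DataFrame       # per genotype x parameter x minute: Wilcoxon vs 100
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.timecourse.to_csv(out / "timecourse.csv", index=False)
        self.tests.to_csv(out / "timecourse_tests.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1,
                                                        sort_keys=True))


def _per_unit_values(rec: Recording, well: str, e_max: int, cfg: RunConfig) -> dict[str, list[float]]:
    bounds = list(rec.unit_boundaries_s) + [rec.duration_s]
    wmfr, nbr = [], []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        unit = rec.restrict(t0, t1)
        sm = _metrics.spike_metrics(unit, well, e_max=e_max, min_rate_hz=cfg.min_rate_hz,
                                    weighting=cfg.wmfr_weighting)
        nbs = _network.detect_network_bursts(
            unit, well, cfg.nb_max_isi_s, cfg.nb_min_spikes, cfg.nb_min_channels
        )
        wmfr.append(sm.wmfr_hz)
        nbr.append(len(nbs) / unit.duration_s)
    return {"wmfr_hz": wmfr, "nb_rate_hz": nbr}


def run_disinhibition(
    baseline: Recording,
    post: Recording,
    grouping: GroupingTable,
    config: RunConfig | None = None,
) -> DisinhibitionResult:
    """Baseline-normalized (100%) per-unit time courses after disinhibition."""
    cfg = config or RunConfig()
    wells, _ = grouping.split_grouped(baseline.wells())
    # e_max fixed at baseline for treatment experiments
    e_max = {
        w: len(_metrics.active_electrodes(baseline, w, cfg.min_rate_hz)) for w in wells
    }
    valid, _reasons = _qc.select_valid_wells(e_max, cfg.min_active)
    rows = []
    n_base = len(baseline.unit_boundaries_s)
    for w in sorted(valid):
        base_vals = _per_unit_values(baseline, w, e_max[w], cfg)
        post_vals = _per_unit_values(post, w, e_max[w], cfg)
        for param in base_vals:
            series = base_vals[param] + post_vals[param]
            try:
                tc = _treatment.baseline_normalize(series, n_base, parameter=param)
            except ValueError:
                continue  # zero baseline; well excluded for this parameter
            for minute, raw, pct in zip(tc.minutes, tc.raw, tc.percent):
                rows.append(
                    {"well": w, "genotype": grouping.genotype_of(w), "parameter": param,
                     "minute": minute, "raw": raw, "percent": pct}
                )
    timecourse = pd.DataFrame(rows)
    test_rows = []
    if not timecourse.empty:
        post_tc = timecourse[timecourse["minute"] >= 0]
        for (gen, param, minute), grp in post_tc.groupby(["genotype", "parameter", "minute"]):
            dev = grp["percent"].to_numpy() - 100.0
            if len(dev) < 3 or np.all(dev == 0):
                continue
            stat, p = sps.wilcoxon(dev)
            test_rows.append(
                {"genotype": gen, "parameter": param, "minute": minute,
                 "test": "wilcoxon_vs_100", "statistic": float(stat),
                 "p_value": float(p), "n": len(dev)}
            )
    return DisinhibitionResult(timecourse, pd.DataFrame(test_rows), cfg.provenance())


@dataclass
class StimResult:
    evoked: pd.DataFrame       # well x block: evmfr_norm, cv, skewness
    tet: pd.DataFrame          # well: X, genotype
    qc_report: pd.DataFrame
    by_genotype: dict[str, tuple[float, float, int]]  # genotype -> (mean X, var X, n)
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.evoked.to_csv(out / "evoked_summary.csv", index=False)
        self.tet.to_csv(out / "tet_effect.csv", index=False)
        self.qc_report.to_csv(out / "qc_report.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1,
                                                        sort_keys=True))


def run_stim(
    blocks: Mapping[str, Recording],
    stim_log: pd.DataFrame,
    grouping: GroupingTable,
    config: RunConfig | None = None,
) -> StimResult:
    """Evoked-activity analysis of one stimulation experiment."""
    cfg = config or RunConfig()
    sa1 = blocks["SA1"]
    wells, _ = grouping.split_grouped(sa1.wells())
    splits = {name: rec.split_wells() for name, rec in blocks.items()}
    qc_rows = []
    # preselection on SA1 activity (8 active electrodes)
    n_active = {
        w: len(_metrics.active_electrodes(splits["SA1"][w], w, cfg.min_rate_hz))
        for w in wells
        if w in splits["SA1"]
    }
    valid, sel_reasons = _qc.select_valid_wells(n_active, cfg.min_active_evoked)
    for w, reason in sel_reasons.items():
        qc_rows.append({"well": w, "status": "excluded", "reason": reason})
    # SA1 vs SA2 stability
    stable = set()
    for w in sorted(valid):
        r1 = [t.size / sa1.duration_s for t in splits["SA1"][w].spikes.trains(w).values()]
        r2 = [
            t.size / blocks["SA2"].duration_s
            for t in splits["SA2"][w].spikes.trains(w).values()
        ]
        keep, reason = _qc.stim_stability_filter(r1, r2, cfg.alpha)
        if keep:
            stable.add(w)
        else:
            qc_rows.append({"well": w, "status": "excluded", "reason": reason})
    # evoked summaries per STIM block
    preceding = {"STIM1": "SA1", "STIM2": "SA2", "STIM3": "SA3"}
    ev_rows = []
    summaries: dict[str, dict[str, _evoked.EvokedSummary]] = {}
    for block in ("STIM1", "STIM2", "STIM3"):
        if block not in blocks:
            continue
        protocol = _evoked.StimProtocol.from_log(stim_log, block)
        summaries[block] = {}
        for w in sorted(stable):
            if w not in splits[block] or w not in splits[preceding[block]]:
                continue
            summ = _evoked.analyze_stim_block(
                splits[block][w], protocol, splits[preceding[block]][w], w,
                window_s=cfg.evoked_window_s, min_rate_hz=cfg.min_rate_hz,
                exclude_stim_electrode=cfg.exclude_stim_electrode,
            )
            summaries[block][w] = summ
            ev_rows.append(
                {"well": w, "genotype": grouping.genotype_of(w), "block": block,
                 "evmfr_norm": summ.evmfr_norm, "cv": summ.cv,
                 "skewness": summ.skewness, "n_values": summ.n_values}
            )
    evoked_df = pd.DataFrame(ev_rows)
    # STIM2/STIM1 outlier screen
    tet_wells = sorted(stable)
    if {"STIM1", "STIM2"} <= summaries.keys():
        s1 = {w: summaries["STIM1"][w].evmfr_norm for w in tet_wells}
        s2 = {w: summaries["STIM2"][w].evmfr_norm for w in tet_wells}
        keep_flags = _qc.stim_outlier_filter(s1, s2, cfg.outlier_fence)
        for w, keep in keep_flags.items():
            if not keep:
                qc_rows.append(
                    {"well": w, "status": "excluded", "reason": "evoked_ratio_outlier"}
                )
        tet_wells = [w for w in tet_wells if keep_flags.get(w, True)]
    # tetanus effect per well
    tet_rows = []
    for w in tet_wells:
        if "STIM2" not in summaries or "STIM3" not in summaries:
            break
        x = _evoked.tet_effect(
            summaries["STIM2"][w].evmfr_norm, summaries["STIM3"][w].evmfr_norm
        )
        if math.isnan(x):
            qc_rows.append({"well": w, "status": "excluded", "reason": "tet_x_undefined"})
            continue
        tet_rows.append({"well": w, "genotype": grouping.genotype_of(w), "x": x})
    tet_df = pd.DataFrame(tet_rows)
    by_genotype = {}
    if not tet_df.empty:
        for gen, grp in tet_df.groupby("genotype"):
            x = grp["x"].to_numpy()
            by_genotype[str(gen)] = (
                float(x.mean()), float(x.var(ddof=1)) if x.size > 1 else 0.0, int(x.size)
            )
    for w in sorted(stable):
        if not any(r["well"] == w for r in qc_rows):
            qc_rows.append({"well": w, "status": "kept", "reason": ""})
    return StimResult(
        evoked=evoked_df,
        tet=tet_df,
        qc_report=pd.DataFrame(qc_rows).sort_values("well").reset_index(drop=True),
        by_genotype=by_genotype,
        provenance=cfg.provenance(),
    )


def aggregate_tet_experiments(
    results: Sequence[StimResult],
    genotypes: tuple[str, str],
    convention: str = "welch",
) -> dict:
    """Aggregate the tetanus effect over independent experiments.

    Returns the aggregate Welch t test on per-experiment (mean, var, n)
    triples plus the one-sample Wilcoxon of the pooled X values against 1.
    """
    g_a, g_b = genotypes
    exp_a = [r.by_genotype[g_a] for r in results if g_a in r.by_genotype]
    exp_b = [r.by_genotype[g_b] for r in results if g_b in r.by_genotype]
    comp = _evoked.welch_aggregate_t(exp_a, exp_b, convention=convention)
    pooled = {}
    for g in genotypes:
        xs = np.concatenate(
            [r.tet.loc[r.tet["genotype"] == g, "x"].to_numpy() for r in results]
        )
        dev = xs - 1.0
        if dev.size >= 3 and not np.all(dev == 0):
            _, p = sps.wilcoxon(dev)
        else:
            p = math.nan
        pooled[g] = {"n": int(xs.size), "mean_x": float(xs.mean()),
                     "wilcoxon_vs_1_p": float(p)}
    return {"welch": comp, "pooled": pooled}


# ---------------------------------------------------------------------------
# CLI


def _recording_from_file(path: Path, unit_duration_s: float = 300.0) -> Recording:
    """Rebuild a Recording from one written spike list.

    The CSV does not carry the recording length, so the number of 5-min
    units is inferred from the last spike time.
    """
    table = read_spike_list(path)
    t_max = table.df["time_s"].max() if table.n_spikes else 0.0
    n_units = max(1, int(np.ceil((t_max + 1e-9) / unit_duration_s)))
    return Recording(
        table,
        duration_s=n_units * unit_duration_s,
        unit_boundaries_s=tuple(k * unit_duration_s for k in range(n_units)),
    )


def _load_timeseries_inputs(input_dir: Path):
    recs = {}
    for f in sorted(input_dir.glob("spikes_DIV*.csv")):
        div = int(f.stem.replace("spikes_DIV", ""))
        recs[div] = _recording_from_file(f)
    return recs


def main(argv: Sequence[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="meapipe", description="Multiwell-MEA network-activity analysis pipeline"
    )
    sub = parser.add_subparsers(dest="command", required=True)

    p_sim = sub.add_parser("simulate", help="generate a synthetic dataset")
    p_sim.add_argument("--kind", choices=("development", "stim", "disinhibition"),
                       default="development")
    p_sim.add_argument("--seed", type=int, default=0)
    p_sim.add_argument("--out", required=True)

    for name in ("timeseries", "disinhibition", "stim"):
        p = sub.add_parser(name, help=f"run the {name} analysis")
        p.add_argument("--input", required=True, help="directory with spike lists")
        p.add_argument("--grouping", help="grouping CSV/XLSX (default: input/grouping.csv)")
        p.add_argument("--out", required=True)
        p.add_argument("--seed", type=int, default=0)
        p.add_argument("--min-active", type=int, default=None)
        p.add_argument("--min-rate", type=float, default=None)

    args = parser.parse_args(argv)
    if args.command == "simulate":
        if args.kind == "development":
            _synth.generate_development_dataset(seed=args.seed).write(args.out)
        elif args.kind == "stim":
            _synth.generate_stim_dataset(seed=args.seed).write(args.out)
        else:
            ds = _synth.generate_disinhibition_dataset(seed=args.seed)
            out = Path(args.out)
            out.mkdir(parents=True, exist_ok=True)
            from .spikeio import write_spike_list

            write_spike_list(ds.baseline.spikes, out / "spikes_baseline.csv")
            write_spike_list(ds.post.spikes, out / "spikes_post.csv")
            ds.grouping.df.reset_index().to_csv(out / "grouping.csv", index=False)
        return 0

    cfg = RunConfig(seed=args.seed)
    if args.min_active is not None:
        cfg.min_active = args.min_active
    if args.min_rate is not None:
        cfg.min_rate_hz = args.min_rate
    input_dir = Path(args.input)
    grouping = read_grouping(args.grouping or input_dir / "grouping.csv")

    if args.command == "timeseries":
        recs = _load_timeseries_inputs(input_dir)
        run_timeseries(recs, grouping, config=cfg).write(args.out)
    elif args.command == "disinhibition":
        base = _recording_from_file(input_dir / "spikes_baseline.csv")
        post = _recording_from_file(input_dir / "spikes_post.csv")
        run_disinhibition(base, post, grouping, cfg).write(args.out)
    else:
        blocks = {
            f.stem.replace("spikes_", ""): _recording_from_file(f)
            for f in sorted(input_dir.glob("spikes_*.csv"))
            if "baseline" not in f.stem and "post" not in f.stem
        }
        stim_log = pd.read_csv(input_dir / "stim_log.csv")
        run_stim(blocks, stim_log, grouping, cfg).write(args.out)
    return 0


if __name__ == "__main__":
    sys.exit(main())
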