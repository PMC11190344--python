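import filecmp

import numpy as np
import pytest

from meapipe import metrics, network
from meapipe.synthdata import (
    DisinhibitionGeneratorConfig,
    GeneratorConfig,
    StimGeneratorConfig,
    generate_development_dataset,
    generate_disinhibition_dataset,
    generate_stim_dataset,
)


def _quiet_cfg(**kw):
    """Small development config with near-zero background for exact counting."""
    defaults = dict(
        n_wells_per_genotype=1,
        div_schedule=(25,),
        n_units=4,
        background_rate_hz={10: 1.0, 33: 1.0},
        burst_rate_per_min={10: 0.0, 33: 0.0},
        nb_rate_per_min={10: 0.0, 33: 0.0},
        genotype_gamma={10: 1.0, 33: 1.0},
        well_sd_log10=0.0,
        div_jitter_log10=0.0,
        dropout_prob=0.0,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestDevelopmentGenerator:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = _quiet_cfg(n_wells_per_genotype=2, burst_rate_per_min={10: 1.0, 33: 1.0},
                         nb_rate_per_min={10: 1.0, 33: 1.0})
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_development_dataset(cfg, seed=5).write(d1)
        generate_development_dataset(cfg, seed=5).write(d2)
        for name in ("spikes_DIV25.csv", "grouping.csv", "ground_truth.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False)

    def test_different_seed_differs(self, tmp_path):
        cfg = _quiet_cfg()
        a = generate_development_dataset(cfg, seed=5)
        b = generate_development_dataset(cfg, seed=6)
        assert a.recordings[25].spikes.n_spikes != b.recordings[25].spikes.n_spikes

    def test_background_rate_recovered_within_3_se(self):
        # lambda = 1 Hz x 16 electrodes x 1200 s: well MFR ~ 16 Hz
        cfg = _quiet_cfg()
        ds = generate_development_dataset(cfg, seed=11)
        rec = ds.recordings[25]
        well = rec.wells()[0]
        m = metrics.spike_metrics(rec, well)
        se = np.sqrt(16 * 1.0 * 1200) / 1200
        assert abs(m.mfr_hz - 16.0) < 3 * se

    def test_nb_count_recovered_within_3_se(self):
        # nu = 2/min over 20 min -> 40 NBs; negligible background
        cfg = _quiet_cfg(
            background_rate_hz={10: 0.02, 33: 0.02},
            nb_rate_per_min={10: 2.0, 33: 2.0},
            nb_channels={10: 8, 33: 8},
        )
        ds = generate_development_dataset(cfg, seed=12)
        rec = ds.recordings[25]
        nbs = network.detect_network_bursts(rec, rec.wells()[0])
        assert abs(len(nbs) - 40) < 3 * np.sqrt(40)

    def test_constructed_events_satisfy_detector_definitions(self):
        cfg = _quiet_cfg(
            background_rate_hz={10: 0.0, 33: 0.0},
            burst_rate_per_min={10: 1.0, 33: 1.0},
            nb_rate_per_min={10: 1.0, 33: 1.0},
            nb_channels={10: 8, 33: 8},
        )
        ds = generate_development_dataset(cfg, seed=13)
        rec = ds.recordings[25]
        well = rec.wells()[0]
        # in the no-background limit every generated single-electrode burst
        # is recovered by the detector (recall 100%)
        n_bursts = len(metrics.detect_well_bursts(rec, well))
        n_nbs = len(network.detect_network_bursts(rec, well))
        assert n_bursts > 0 and n_nbs > 0
        for nb in network.detect_network_bursts(rec, well):
            assert nb.n_spikes >= 50
            assert len(nb.channels) >= 5
            assert np.all(np.diff(nb.times_s) <= 0.100 * (1 + 1e-9))

    def test_dropout_electrodes_stay_below_active_threshold(self):
        cfg = _quiet_cfg(dropout_prob=1.0)
        ds = generate_development_dataset(cfg, seed=14)
        rec = ds.recordings[25]
        well = rec.wells()[0]
        assert metrics.active_electrodes(rec, well) == set()
        assert all(ds.truth[25][w].dropout for w in ds.truth[25])

    def test_genotype_gamma_scales_mutant_rates(self):
        cfg = _quiet_cfg(n_wells_per_genotype=4, div_schedule=(12,),
                         genotype_gamma={10: 2.0, 33: 2.0})
        ds = generate_development_dataset(cfg, seed=15)
        lam = {ds.grouping.genotype_of(w): t.lam for w, t in ds.truth[12].items()}
        assert lam["mutant"] == pytest.approx(2 * lam["control"])

    def test_grouping_covers_all_wells_once(self):
        cfg = _quiet_cfg(n_wells_per_genotype=30, div_schedule=(12,))
        ds = generate_development_dataset(cfg, seed=16)
        assert len(ds.grouping.wells) == 60
        assert len(set(ds.grouping.wells)) == 60
        assert set(ds.recordings[12].wells()) <= set(ds.grouping.wells)


class TestStimGenerator:
    def test_blocks_and_log_shapes(self):
        cfg = StimGeneratorConfig(n_wells_per_genotype=1, n_sessions=2,
                                  sa1_duration_s=60.0, sa_mid_duration_s=60.0,
                                  session_duration_s=30.0)
        ds = generate_stim_dataset(cfg, seed=1)
        assert set(ds.blocks) == {"SA1", "STIM1", "SA2", "STIM2", "TET", "SA3", "STIM3"}
        log = ds.stim_log
        assert set(log["block"]) == {"STIM1", "STIM2", "STIM3"}
        # 0.2 Hz over 30 s -> 6 pulses per session
        assert len(log[(log["block"] == "STIM1") & (log["session"] == 1)]) == 6

    def test_evoked_gain_raises_post_pulse_rate(self):
        cfg = StimGeneratorConfig(
            n_wells_per_genotype=1, n_sessions=2, sa1_duration_s=300.0,
            sa_mid_duration_s=60.0, evoked_gain={"control": 4.0, "mutant": 4.0},
            post_tet_gain={"control": 4.0, "mutant": 4.0}, gain_jitter_log10=0.0,
            well_sd_log10=0.0,
        )
        ds = generate_stim_dataset(cfg, seed=2)
        stim = ds.blocks["STIM1"]
        well = stim.wells()[0]
        pulses = ds.stim_log[ds.stim_log["block"] == "STIM1"]["pulse_time_s"].to_numpy()
        train = np.concatenate(list(stim.spikes.trains(well).values()))
        in_win = sum(np.count_nonzero((train >= p) & (train < p + 1.0)) for p in pulses)
        rate_in = in_win / pulses.size / 16  # per electrode Hz
        assert rate_in == pytest.approx(4.0 * cfg.background_rate_hz, rel=0.2)

    def test_determinism(self):
        cfg = StimGeneratorConfig(n_wells_per_genotype=1, n_sessions=1,
                                  sa1_duration_s=60.0, sa_mid_duration_s=30.0,
                                  session_duration_s=30.0)
        a = generate_stim_dataset(cfg, seed=3)
        b = generate_stim_dataset(cfg, seed=3)
        for block in a.blocks:
            assert a.blocks[block].spikes.df.equals(b.blocks[block].spikes.df)


class TestDisinhibitionGenerator:
    def test_step_gain_applied_post_only(self):
        cfg = DisinhibitionGeneratorConfig(
            n_wells_per_genotype=1, well_sd_log10=0.0, nb_rate_per_min=0.0,
            treatment_gain={"control": 2.0, "mutant": 2.0},
        )
        ds = generate_disinhibition_dataset(cfg, seed=4)
        well = ds.baseline.wells()[0]
        base_rate = ds.baseline.spikes.well(well).shape[0] / ds.baseline.duration_s
        post_rate = ds.post.spikes.well(well).shape[0] / ds.post.duration_s
        assert post_rate / base_rate == pytest.approx(2.0, rel=0.1)
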