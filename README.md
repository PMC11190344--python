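# meapipe

Analysis pipeline for longitudinal multiwell multielectrode-array (MEA)
recordings of developing neuronal networks, written for electrophysiologists
who record cultured cortical neurons on multiwell plates (48 wells × 16
electrodes) and want a scripted, reproducible path from vendor spike lists to
genotype-level statistics.

The pipeline covers:

* **Spike-list I/O** — CSV spike lists (one row per spike: time in seconds,
  `well_electrode` label, amplitude in mV), concatenation of 5-minute
  recording units, binary timestamp matrices at the 12.5 kHz acquisition rate
  (one sample = 0.08 ms).
* **Spontaneous-activity metrics** per well: mean firing rate
  MFR = n_spikes/s, the weighted rates wMFR = (e_max/e_act)·MFR and wtMFR
  (weighting to all 16 electrodes), mean inter-spike interval, burst
  detection (≥ 5 consecutive spikes with every ISI ≤ 100 ms) with MBR and
  wMBR = (e_act/e_max)·MBR, network bursts (≥ 50 pooled spikes, pooled
  ISIs ≤ 100 ms, ≥ 5 channels), and the spike time tiling coefficient

  STTC = ½ [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ],

  with mean and skewness over all electrode pairs. An electrode is *active*
  at ≥ 0.1 Hz.
* **Quality control** — well selection by active-electrode count at a
  reference timepoint (≥ 10; 8 for evoked experiments), longitudinal
  integrity censoring (≥ 2-channel drop **and** wMFR < 70 % of reference),
  stability and outlier screens for stimulation experiments. Every exclusion
  carries a machine-readable reason code.
* **PCA cluster separation** — per-timepoint z-scoring, correlation PCA of
  19-dimensional parameter vectors, and genotype separation in the PC1–PC2
  plane via Mahalanobis distance D and Hotelling's two-sample T²,
  F = (n−p−1)/((n−2)p) · T² with dof (p, n−p−1); feature-specific PC1
  projections for spiking, bursting and network bursting.
* **Evoked activity** — post-pulse firing in 1-s windows normalized to
  same-electrode spontaneous rate (evMFR_norm), and the tetanus effect
  X = log₁₀(evMFR_norm@STIM3) / log₁₀(evMFR_norm@STIM2) with an aggregate
  Welch t test across independent experiments.
* **Disinhibition time courses** — per-5-min-unit parameters as percent of
  the 20-min pre-treatment baseline (100 %).
* **Synthetic data** — a generator producing spike lists with the same
  statistical structure (developmental rate increase, bursts, network
  bursts, genotype effects that fade with maturation, electrode dropout,
  evoked gains) plus ground truth, so the whole pipeline is testable
  without recordings.

## Worked example

```python
from meapipe.synthdata import GeneratorConfig, generate_development_dataset
from meapipe.pipeline import RunConfig, run_timeseries
from meapipe.spikeio import CohortMap

cohorts = CohortMap.from_ranges(
    {"a_DIV11-13": (11, 13), "b_DIV21-23": (21, 23), "c_DIV29-31": (29, 31)}
)
cfg = GeneratorConfig(n_wells_per_genotype=20,
                      div_schedule=(11, 13, 21, 23, 29, 31), n_units=2)
ds = generate_development_dataset(cfg, seed=101)
res = run_timeseries(ds.recordings, ds.grouping, cohorts=cohorts,
                     config=RunConfig(reference_window=(21, 23)))
print(res.separations[["cohort", "mahalanobis_d", "f_value", "p_value"]])
```

prints (seed 101):

```
       cohort  mahalanobis_d    f_value   p_value
0  a_DIV11-13       1.363235  14.967579  0.000005
1  b_DIV21-23       0.854118   5.875514  0.004574
2  c_DIV29-31       0.316774   0.808181  0.450234
```

The mutant genotype (simulated with a 1.5× rate excess that fades by
DIV 24) separates strongly from its control at DIV 11–13 — the F value is
far above the two-component critical value 3.1 — and the separation decays
toward chance level as the networks mature, reproducing the convergent
developmental phenotype the pipeline is designed to quantify. The same
result object carries the per-well metrics table, the QC report with reason
codes, feature-specific PC1 projections and per-parameter Mann–Whitney
tests with Wendt's r.

A command-line interface mirrors the library:

```sh
meapipe simulate --kind development --seed 1 --out data/
meapipe timeseries --input data/ --out results/
```

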