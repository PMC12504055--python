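# qmapkit

Quantitative multiparametric MRI relaxometry as a tested, desk-scale
pipeline: simulation of a 5-contrast magnetization-prepared acquisition,
dictionary-based voxelwise T1/T2 map fitting, NIST-style system-phantom
benchmarking statistics, and longitudinal ROI delta analysis for
radiotherapy treatment-response assessment.

The package is aimed at medical physicists and imaging scientists who
want to reason quantitatively about a rapid T1/T2 mapping sequence —
its accuracy, repeatability and sensitivity to longitudinal tissue
change — without access to scanner data: a synthetic-data module
generates a digital 14-vial phantom over repeated sessions and aligned
longitudinal patient-like volumes with exactly known ground truth.

## The model and the statistics

**Signal model.** The sequence acquires five 3D contrasts per scan: a
steady-state proton-density-weighted (PDw) spoiled-gradient-echo (SPGR)
readout at a very low flip angle (~1°), then a magnetization-prepared
train read out at 3°: one segment after a T2 preparation
(`mz ← mz · e^(−TE_prep/T2)`) and three segments at increasing delays
after an inversion (T1) preparation. Within a readout segment each
excitation maps the longitudinal magnetization through
`mz ← cos(α)·e^(−TR/T1)·mz + (1 − e^(−TR/T1))`; every cycle element is
affine in `mz`, so the periodic steady state of the composed cycle map
`mz ← a·mz + b` is the closed form `mz* = b/(1 − a)`.

**Map fitting.** A measured 5-vector `y` is matched against a dictionary
of unit-norm simulated atoms `d(T1, T2)` by maximizing `|⟨y, d⟩|` — the
single-atom limit of orthogonal matching pursuit, exactly equivalent to
per-atom least squares with one free scale. The scale is a
proton-density surrogate; the residual is `√(1 − cos²θ)`.

**Benchmarking.** Vials are segmented automatically on the PDw volume
(Otsu threshold → connected components → template assignment) and
measured as the mean within a 5-mm-radius spherical ROI. Accuracy is
bias versus reference (ms and %), repeatability the coefficient of
variation `CV = SD/mean` (sample SD; intrasession over repeats,
intersession over session means), linearity an ordinary least-squares
regression of derived on reference values inside the physiological
window (T1 245.8–1741.3 ms, T2 42–493 ms).

**Response analysis.** Maps are masked by Otsu background removal and a
seed-fill airway mask; per-ROI means, medians, SDs, skewness and
fixed-edge histograms feed a delta analysis versus the pre-treatment
baseline (`Δms`, `Δ% = Δms/baseline·100`), the within-subject
`wCV = SD/mean` over all timepoints, and a residual-disease versus
initial-disease histogram comparison.

## Worked example

```python
import pandas as pd
import qmapkit as qk

# simulate one tissue and fit it back through the dictionary
timing = qk.SequenceTiming()
dictionary = qk.build_dictionary(qk.DEFAULT_T1_GRID, qk.DEFAULT_T2_GRID, timing)
signal = qk.simulate_contrast_vector(qk.TissueParams(t1=962.0, t2=98.0), timing)
t1, t2, scale, residual = qk.match_voxel(signal, dictionary)
print(f"fitted: T1 = {t1:.1f} ms, T2 = {t2:.1f} ms")

# longitudinal delta analysis of a control ROI's per-timepoint means
means = pd.DataFrame({
    "roi": "NAWM",
    "timepoint": ["PreTx", "PostTx1", "PostTx2"],
    "mean": [678.0, 687.0, 701.0],
})
report = qk.delta_analysis(means, baseline_label="PreTx")
print(report.deltas[["timepoint", "delta_ms", "delta_pct"]].round(1))
print(report.wcv.round(1))
```

prints

```
fitted: T1 = 960.0 ms, T2 = 98.0 ms
timepoint  delta_ms  delta_pct
  PostTx1       9.0        1.3
  PostTx2      23.0        3.4
 roi  wcv_pct  n_timepoints
NAWM      1.7             3
```

The fitted T1 lands on the grid node nearest the true 962 ms (10-ms
spacing in that range). The control ROI drifts by +9 ms (+1.3%) and
+23 ms (+3.4%) relative to baseline with a within-subject CV of 1.7% —
the scale of longitudinal stability expected of uninvolved tissue.

## Command line

Five commands tie the stages together with NIfTI/CSV/JSON/YAML I/O
(`qmapkit --help`): `simulate-phantom`, `simulate-subject`, `fit-maps`,
`benchmark`, `delta-analysis`. Each takes `--config` (YAML), `--seed`,
`--out` and `--log-level`, and writes the resolved configuration and a
provenance line (version, seed, config hash) beside its outputs.
`benchmark` and `delta-analysis` accept either injected measurement/mean
CSVs or `--simulate` to run the full synthetic pipeline.

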