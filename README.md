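# hrrlab

Heart-rate recovery (HRR) and heart-rate variability (HRV) analysis for
exercise-test cohorts, from beat-by-beat RR series through recovery
statistics, tri-method spectral analysis, and cohort-level statistical
comparison — plus a seeded synthetic cohort generator so the whole pipeline is
testable without any recordings.

## What it does

- **`hrrlab.synthetic`** — seeded synthetic exercise tests. Each subject's
  instantaneous HR follows rest → linear ramp → mono-exponential recovery
  (`plateau + (peak − plateau)·e^(−t/τ)`); sinusoidal LF/HF modulation and
  white noise are applied in the RR domain and beats are emitted by integral
  pulse frequency modulation (IPFM). Group kinetics and metadata
  distributions default to published cohort summary statistics, with the
  recovery plateau/τ calibrated to the reported 1/2/3-minute recovery HRs.
  Optional ectopic-beat injection for testing artifact filtering.
- **`hrrlab.preprocessing`** — RR tachograms from beat times, artifact
  rejection (300–2000 ms bounds, 20% delta rule; interpolation for spectra,
  deletion for HR means), centered 10-beat windowed HR, resting/peak HR, and
  4 Hz cubic-spline resampling.
- **`hrrlab.hrr`** — the nine per-subject recovery statistics (absolute HR
  drop at 1/2/3 min, normalized to peak HR and to heart-rate reserve) and the
  abnormal-blood-pressure-response classifier.
- **`hrrlab.spectral`** — Welch, autoregressive (Levinson–Durbin), and
  Lomb–Scargle PSD estimators over the first 3 minutes of recovery, reduced
  to VLF/LF/HF band powers, normalized units (`lf_nu + hf_nu = 1` exactly),
  and the LF:HF ratio.
- **`hrrlab.stats`** — normality-gated group comparisons (pooled t /
  ANOVA + Bonferroni vs Mann–Whitney / Kruskal–Wallis), Fisher's exact test,
  OLS with backward elimination, the pooled-cohort model (Model 1) and the
  patient-only two-stage disease-severity model (Model 2), and a group
  summary table.
- **`hrrlab.io` / `hrrlab.cli`** — plain-CSV beat and metadata dialects,
  YAML config echo, end-to-end orchestration with a machine-readable
  exclusion log.

## CLI

```bash
# generate a synthetic cohort (beat CSV + metadata CSV + config echo)
hrrlab simulate --seed 1 --out-dir out/sim

# per-subject HRR metrics and band powers
hrrlab analyze --beats out/sim/beats.csv --metadata out/sim/metadata.csv --out-dir out/ana

# one subject's PSD export
hrrlab spectra --beats out/sim/beats.csv --subject con-000 --method welch --out out/psd.csv

# full cohort statistics: summary table, regression report, exclusion log
hrrlab compare --beats out/sim/beats.csv --metadata out/sim/metadata.csv --out-dir out/cmp
```

Beat CSV dialect: header `subject_id,beat_time_s,phase` with strictly
increasing times per subject and phases contiguous in the order
`rest → exercise → recovery`.

## Layout

```
src/hrrlab/     synthetic.py  preprocessing.py  hrr.py  spectral.py
                stats.py  records.py  io.py  cli.py  errors.py
tests/          unit + property tests per module, test_acceptance.py
scripts/        acceptance.py
```
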