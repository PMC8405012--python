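# hrnv

Heart rate n-variability (HRnV) analysis toolkit: extract time-domain,
spectral and nonlinear variability parameters from R-R interval tachograms
and their combined-interval generalizations, and run a complete
risk-modelling workflow (two-group baseline statistics, univariable
screening, collinearity pruning, backward stepwise logistic regression,
and cross-validated ROC evaluation against bedside early-warning scores).

A synthetic-data module generates tachograms (via integral pulse frequency
modulation), ECG waveforms, and two-group cohorts with known ground truth,
so every stage of the pipeline is testable without external data.

## Layout

| module | purpose |
|---|---|
| `hrnv.synthetic` | IPFM tachograms, template-beat ECGs, logistic-outcome cohorts |
| `hrnv.sequences` | R-peak detection, signal quality, RRnI / RRnI_m windowed-sum sequences |
| `hrnv.params` | the ~26-parameter suite per sequence (SDNN, RMSSD, NN50n/pNN50n, Lomb–Scargle band powers, Poincaré, SampEn/ApEn, DFA, …) |
| `hrnv.cohort` | normality-gated two-group tests, Yates χ² / Fisher, median imputation, baseline table |
| `hrnv.model` | univariable logistic screen, collinearity pruning, backward stepwise selection |
| `hrnv.evaluation` | stratified k-fold out-of-fold scoring, Mann–Whitney AUC with DeLong/bootstrap CIs, NEWS/MEWS/qSOFA calculators |

## CLI

```bash
# synthesize a tachogram + ECG + cohort from a YAML config
hrnv simulate --config sim.yaml --out outdir --seed 1

# parameter suite from an interval file (one ms value per line) or ECG CSV
hrnv extract --input outdir/rri.txt --nmax 3 --out features.csv
hrnv extract --input outdir/ecg.csv --format ecg --out features.csv

# baseline table, selection pipeline, cross-validated ROC comparison
hrnv analyze --cohort cohort.csv --baseline --model --evaluate \
             --folds 10 --seed 1 --out results/
```

Example `sim.yaml`:

```yaml
tachogram: {duration_s: 300, mean_hr: 70, lf_amp: 0.05, hf_amp: 0.05, noise_sd: 5}
ecg: {sampling_rate: 250.0, noise_sd: 0.02}
cohort: {n_patients: 342, prevalence: 0.19, n_noise_features: 5}
```

## Notes

- Spectral band edges default to VLF 0.0033–0.04, LF 0.04–0.15,
  HF 0.15–0.40 Hz and are applied unchanged to all combined sequences;
  both choices are configurable (`hrnv.params.SpectralBands`).
- Sample entropy emits a documented sentinel (1000.0) plus a degeneracy
  flag when no length-(m+1) template matches exist, rather than crashing on
  short sequences.
- pNN50 uses the number of successive differences as its denominator by
  default; the element count is available via
  `time_domain(..., denominator="elements")`.
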