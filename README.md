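# noctivitals

Nocturnal vital-sign analytics for remote screening of chronic obstructive
pulmonary disease (COPD).

Under-mattress piezoelectric sensors can record heartbeat intervals and
respiratory rate every night, at home, for weeks. Because any single night is
contaminated by mood, activity and environment, a diagnostic signal emerges
only after aggregating nightly features across many nights. `noctivitals`
implements that analysis end to end for researchers in remote monitoring and
biostatistics:

* **simulation** of multi-night case/control cohorts — beat-interval
  tachograms with controlled spectral band powers, per-minute respiratory-rate
  series with tachypnea episodes, imperfect compliance, quality-control (QC)
  violations and acute-exacerbation windows;
* **feature extraction** per night: SDNN, Lomb–Scargle band powers (TP, ULF,
  VLF, LF, HF, LF/HF; ms²), modal heart rate and respiratory rate, and RRF —
  the minutes per night with respiratory rate above 21 breaths/min;
* **QC exclusions**: ≥600 artifact motions, sleep under 5 h or over 9 h,
  ≥1 h data loss, zero heart/respiratory rate, and nights from 7 days before
  through the end of an acute exacerbation;
* **multiday aggregation**: rolling t-day trimmed means,
  (Σ − max − min)/(t − 2), for t ∈ {1, 7, 14, 30};
* **diagnostics**: Mann–Whitney feature screening, unregularized logistic
  regression (also exposed as the sklearn-compatible
  `NocturnalVitalsClassifier`), ROC/AUC with DeLong confidence intervals and
  paired AUC tests, and Youden-index cutoffs (J = sensitivity + specificity − 1);
* **sample-size estimation** for sensitivity/specificity precision designs.

## Worked example

```python
import noctivitals as nv

# the precision design: Se = Sp = 0.90, 10% relative tolerance, alpha = .01,
# one case per two controls
print(nv.required_sizes(nv.SampleSizeSpec()))
# SampleSizeResult(n_cases=37, n_controls=74, n_total=111,
#                  n_cases_inflated=42, n_controls_inflated=83,
#                  n_total_inflated=125, driver='specificity')

# a simulated 100-person study, 60 scheduled nights each
config = nv.StudyConfig(
    simulation=nv.SimulationConfig(n_cases=50, n_controls=50,
                                   nights_per_person=60, seed=9)
)
report = nv.run_study(config)
print(report.evaluation[["feature_set", "t", "accuracy", "auc"]]
      .query("t == 7").to_string(index=False))
#  feature_set   t  accuracy      auc
#          all 7.0  0.925891 0.978146
#          hrv 7.0  0.791938 0.876519
#           hr 7.0  0.618295 0.665529
#  respiration 7.0  0.903256 0.961253
```

Reading the output: at the 7-day timescale the combined feature panel
classifies case vs control person-time samples with AUC 0.98; respiration
features (rate and tachypnea minutes) outperform the HRV panel, and modal
heart rate alone is a weak classifier — the ordering the nightly-monitoring
design is built around. `report.cutoffs` additionally lists raw-scale
Youden-optimal cutoffs for the three leading features (HF, RR, RRF), and
`report.screening` shows the LF/HF ratio failing the group-difference screen
(cases have LF and HF elevated proportionally, so their ratio carries no
signal).

A command-line interface mirrors the library
(`noctivitals simulate | extract | qc | aggregate | evaluate | samplesize |
run-all`); see `noctivitals --help`.

## Layout

| module | contents |
| --- | --- |
| `noctivitals.simulate` | cohort, tachogram and respiration generators; CSV persistence |
| `noctivitals.spectral` | fast Lomb–Scargle periodogram, band-power integration |
| `noctivitals.hrv`, `noctivitals.respiration` | nightly feature extraction |
| `noctivitals.qc` | night-level exclusion rules |
| `noctivitals.aggregate` | trimmed-mean person-time samples |
| `noctivitals.diagnostics` | rank/χ² tests, logistic fit, ROC/DeLong/Youden |
| `noctivitals.estimator` | sklearn-compatible classifier wrapper |
| `noctivitals.samplesize` | precision-design sample sizes |
| `noctivitals.pipeline`, `noctivitals.cli` | orchestration and CLI |

Methodological details — the generative model, estimator choices, numerical
conventions and limitations — are documented in
[`docs/methods.md`](docs/methods.md).
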