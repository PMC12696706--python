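# docbci

Synthetic-EEG analysis pipeline for motor-imagery brain–computer
interface (MI-BCI) assessment of prolonged disorders of consciousness
(pDoC).

## The problem

Patients with pDoC — unresponsive wakefulness syndrome (UWS) and the
minimally conscious state (MCS) — cannot communicate behaviorally, so
consciousness level is hard to grade at the bedside. A closed-loop
MI-BCI offers an electrophysiological probe: the patient is cued to
imagine clenching a fist while 30-channel scalp EEG is recorded; when a
prefrontal attention index crosses a threshold, a pneumatic glove closes
the hand as feedback. Two families of readouts separate the groups:

* **Relative band power.** Welch power spectral density per channel,
  normalized per band over the 1–45 Hz range,

  `Power_rel(band) = Σ_{f1≤f<f2} P(f) / Σ_{1≤f≤45} P(f)`,

  aggregated over frontal/parietal/temporal/occipital channel groups and
  over the five bands delta (1–4 Hz), theta (4–8), alpha (8–15),
  beta (15–30), gamma (30–45). MCS-like subjects modulate many bands
  during imagery (delta/theta up, alpha/beta/gamma down over
  frontoparietal cortex); UWS-like subjects show only a parietal gamma
  increase.
* **Closed-loop metrics.** The attention index `R = E_beta / E_alpha` at
  Fp1, normalized per subject to a 0–100 scale; a trial succeeds when
  the moving average of the index exceeds 50 inside the imagery window.
  Classification accuracy = successful / attempted trials, and the
  session-mean index correlates with the behavioral CRS-R score
  (Spearman's rho).

Because clinical recordings of this kind are not publicly deposited, the
package is built around a **synthetic-EEG generator** that emulates the
two groups (band-power composition, cue-locked task modulation, ocular
and movement artifacts, CRS-R-linked attention responsiveness), so every
stage of the analysis is testable against ground truth. Group-level
comparisons use the Wilcoxon rank-sum / signed-rank tests (with exact
small-sample enumeration), Welch's t, Pearson's chi-square, and Spearman
correlation with bootstrap CIs.

## Worked example

```python
from docbci import (SessionPlan, make_cohort, run_cohort_sessions,
                    run_cohort_spectra, build_contrast_tables)
from docbci.stats import spearman_rho

plan = SessionPlan(n_trials=15, n_practice=5, rest_duration_s=60.0)
cohort = make_cohort(n_uws=12, n_mcs=19, seed=42)

sessions, trials, traces = run_cohort_sessions(cohort, plan, seed=42)
print(sessions.groupby("group").accuracy_pct.mean().round(1))
corr = spearman_rho(sessions.mean_attention_index, sessions.crs_r)
print(f"rho = {corr.rho:.2f}, p = {corr.p:.3f}")
```

prints

```
group
MCS    71.6
UWS    38.3
Name: accuracy_pct, dtype: float64
rho = 0.54, p = 0.002
```

— the MCS-like group triggers the glove in roughly two of three trials
versus just over one in three for the UWS-like group (this seed's
cohort draws on the high side for MCS; across seeds the group means
fluctuate around 60% and 36%), and the session-mean attention index
tracks the CRS-R score with a moderate positive rank correlation
(0.44 on average over replicate cohorts).

The same cohort's spectral contrasts:

```python
rpt = run_cohort_spectra(cohort, plan, seed=42)
tables = build_contrast_tables(rpt)
w = tables["table2_within"].set_index(["region", "band", "group"])
print(w.loc[("parietal", "theta", "MCS")][["rest_median", "task_median", "p"]])
```

shows the parietal theta increase under the task (rest median ≈ 0.26,
task median ≈ 0.34, signed-rank p < 0.001 at n = 19).

A full reproducible run (recordings → QC → spectra → BCI → statistics,
with a manifest and config-hashed CSV outputs) is one command:

```bash
docbci all --outdir runs/demo --seed 7
docbci validate --outdir runs/demo
```

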